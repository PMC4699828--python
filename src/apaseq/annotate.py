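"""Genomic annotation of called poly(A) sites.

Each site is assigned the first matching category in a fixed precedence
order: 3'UTR, exon (CDS), intron, 5'UTR, downstream (10 kb past the gene's
3' end), non-coding gene, mitochondrial, antisense, intergenic.  All
gene-linked categories are matched on the same strand (3'-end libraries are
strand-specific); only antisense looks at the opposite strand.  Sites
landing on a mitochondrial chromosome without an earlier match are flagged
for exclusion from downstream analyses.

Sites are additionally classified as ``known`` (within 30 bp of an annotated
3'UTR end), ``db_supported`` (within a tolerance of a reference poly(A)-site
database entry, e.g. EST-derived collections), or ``novel``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from apaseq.cluster import PolyASite
from apaseq.io_formats import GeneModel

CATEGORY_ORDER = (
    "3UTR",
    "exon",
    "intron",
    "5UTR",
    "downstream",
    "ncRNA",
    "mitochondrial",
    "antisense",
    "intergenic",
)

DOWNSTREAM_NT = 10_000


@dataclass
class SiteAnnotation:
    category: str
    host_gene: str | None = None
    novelty: str | None = None
    excluded: bool = False


@dataclass
class AnnotationIndex:
    """Interval indexes per category plus annotated 3'UTR ends and DB sites."""

    trees: dict[str, dict[tuple[str, str], IntervalTree]] = field(default_factory=dict)
    gene_spans: dict[tuple[str, str], IntervalTree] = field(default_factory=dict)
    utr_ends: dict[tuple[str, str], list[tuple[int, str]]] = field(default_factory=dict)
    db_sites: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    mito_chroms: frozenset[str] = frozenset({"chrM", "MT"})
    utr_end_by_gene: dict[str, int] = field(default_factory=dict)

    def _tree(self, category: str, chrom: str, strand: str) -> IntervalTree:
        per_cat = self.trees.setdefault(category, {})
        key = (chrom, strand)
        if key not in per_cat:
            per_cat[key] = IntervalTree()
        return per_cat[key]


def build_annotation_index(
    gene_models: Iterable[GeneModel],
    mito_chroms: Iterable[str] = ("chrM", "MT"),
    db_sites: Iterable[tuple[str, int, str]] = (),
) -> AnnotationIndex:
    """Index gene models (and an optional poly(A)-site database) for annotation.

    For coding genes, each exon nucleotide falls in exactly one of
    5'UTR / CDS-exon / 3'UTR in transcript orientation; introns are the gene
    span minus the exons; the downstream region is the 10 kb past the gene's
    3' terminus.  lncRNA genes index their whole exonic span as ``ncRNA``.
    """
    idx = AnnotationIndex(mito_chroms=frozenset(mito_chroms))
    for g in gene_models:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        key = (g.chrom, g.strand)
        idx.gene_spans.setdefault(key, IntervalTree()).addi(g.start, g.end, g.gene_id)
        # introns
        for (s0, e0), (s1, e1) in zip(g.exons, g.exons[1:]):
            if s1 > e0:
                idx._tree("intron", g.chrom, g.strand).addi(e0, s1, g.gene_id)
        if g.biotype == "coding":
            lo, hi = (g.cds_start, g.cds_end) if g.strand == "+" else (g.cds_end, g.cds_start)
            for es, ee in g.exons:
                for cat, (cs, ce) in {
                    "5UTR" if g.strand == "+" else "3UTR": (es, min(ee, lo)),
                    "exon": (max(es, lo), min(ee, hi)),
                    "3UTR" if g.strand == "+" else "5UTR": (max(es, hi), ee),
                }.items():
                    if ce > cs:
                        idx._tree(cat, g.chrom, g.strand).addi(cs, ce, g.gene_id)
        else:
            for es, ee in g.exons:
                idx._tree("ncRNA", g.chrom, g.strand).addi(es, ee, g.gene_id)
        # downstream: 10 kb past the transcript 3' terminus
        if g.strand == "+":
            idx._tree("downstream", g.chrom, g.strand).addi(g.end, g.end + DOWNSTREAM_NT, g.gene_id)
            utr_end = g.annotated_utr_ends[-1] if g.annotated_utr_ends else g.end - 1
        else:
            idx._tree("downstream", g.chrom, g.strand).addi(
                max(0, g.start - DOWNSTREAM_NT), g.start, g.gene_id
            )
            utr_end = g.annotated_utr_ends[0] if g.annotated_utr_ends else g.start
        idx.utr_end_by_gene[g.gene_id] = utr_end
        for p in g.annotated_utr_ends or [utr_end]:
            idx.utr_ends.setdefault(key, []).append((p, g.gene_id))
    for key in idx.utr_ends:
        idx.utr_ends[key].sort()
    for chrom, pos, strand in db_sites:
        idx.db_sites.setdefault((chrom, strand), []).append(pos)
    for key in idx.db_sites:
        idx.db_sites[key].sort()
    return idx


def _hits(idx: AnnotationIndex, category: str, chrom: str, strand: str, pos: int) -> list[str]:
    per_cat = idx.trees.get(category, {})
    tree = per_cat.get((chrom, strand))
    if tree is None:
        return []
    return [iv.data for iv in tree.at(pos)]


def _nearest_gene(idx: AnnotationIndex, genes: Sequence[str], pos: int) -> str:
    """Among candidate genes, the one whose 3'UTR end is nearest (tie: gene_id)."""
    return min(genes, key=lambda g: (abs(idx.utr_end_by_gene.get(g, pos) - pos), g))


def annotate_site(site: PolyASite, index: AnnotationIndex) -> SiteAnnotation:
    """Assign the first matching category in the fixed precedence order."""
    for category in ("3UTR", "exon", "intron", "5UTR", "downstream", "ncRNA"):
        genes = _hits(index, category, site.chrom, site.strand, site.position)
        if genes:
            return SiteAnnotation(category, host_gene=_nearest_gene(index, genes, site.position))
    if site.chrom in index.mito_chroms:
        return SiteAnnotation("mitochondrial", excluded=True)
    anti = "-" if site.strand == "+" else "+"
    tree = index.gene_spans.get((site.chrom, anti))
    if tree is not None and tree.at(site.position):
        genes = [iv.data for iv in tree.at(site.position)]
        return SiteAnnotation("antisense", host_gene=_nearest_gene(index, genes, site.position))
    return SiteAnnotation("intergenic")


def _nearest_distance(sorted_pos: Sequence, pos: int, key=lambda x: x) -> int | None:
    if not sorted_pos:
        return None
    i = bisect.bisect_left([key(x) for x in sorted_pos], pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(sorted_pos):
            d = abs(key(sorted_pos[j]) - pos)
            best = d if best is None else min(best, d)
    return best


def classify_novelty(
    site: PolyASite,
    index: AnnotationIndex,
    tol_known: int = 30,
    tol_db: int = 30,
) -> str:
    """known (near an annotated 3'UTR end) / db_supported (near a DB site) / novel."""
    key = (site.chrom, site.strand)
    d = _nearest_distance(index.utr_ends.get(key, []), site.position, key=lambda x: x[0])
    if d is not None and d <= tol_known:
        return "known"
    d = _nearest_distance(index.db_sites.get(key, []), site.position)
    if d is not None and d <= tol_db:
        return "db_supported"
    return "novel"


def annotate_sites(
    sites: Iterable[PolyASite],
    index: AnnotationIndex,
    tol_known: int = 30,
    tol_db: int = 30,
) -> list[SiteAnnotation]:
    """Annotate every site in place (category, host gene, novelty) and return the records."""
    out = []
    for s in sites:
        ann = annotate_site(s, index)
        ann.novelty = classify_novelty(s, index, tol_known, tol_db)
        s.annotation_category = ann.category
        s.host_gene = ann.host_gene
        s.novelty_class = ann.novelty
        out.append(ann)
    return out
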