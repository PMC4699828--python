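"""Gene-level expression and differential-expression calls.

Gene boundaries are the annotated gene spans extended downstream (transcript
orientation) by at most 3,000 nt without creating overlap with a neighbour;
when two extensions compete for one gap the gap is split at its midpoint.
Gene expression is the sum of poly(A)-cluster expression (RPM) over sites
inside the boundary.  Differential expression between two samples uses a
two-sided Fisher's exact test on read counts against library totals,
Benjamini-Hochberg FDR across genes within each pairwise comparison, and a
fold-change filter on pseudocount-stabilised RPM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, pearsonr
from statsmodels.stats.multitest import multipletests

from apaseq.cluster import PolyASite
from apaseq.io_formats import GeneModel

MAX_EXTENSION_NT = 3000


@dataclass
class GeneBoundary:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def gene_boundaries(
    gene_models: Sequence[GeneModel], max_ext: int = MAX_EXTENSION_NT
) -> list[GeneBoundary]:
    """Extend each gene downstream by up to ``max_ext`` nt without overlap.

    Only a gene whose transcript 3' end faces a gap competes for that gap;
    when the two flanking genes both extend into it, the gap is split at its
    midpoint, the extra nucleotide of an odd gap going to the left-hand gene.
    Raises if the annotated genes already overlap.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(gene_models, key=lambda m: (m.chrom, m.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    overlaps = []
    out: list[GeneBoundary] = []
    for chrom, genes in by_chrom.items():
        for a, b in zip(genes, genes[1:]):
            if b.start < a.end:
                overlaps.append((a.gene_id, b.gene_id))
        if overlaps:
            continue
        ext_right = [0] * len(genes)  # extension past gene.end
        ext_left = [0] * len(genes)  # extension before gene.start
        for i, (a, b) in enumerate(zip(genes, genes[1:])):
            gap = b.start - a.end
            left_wants = a.strand == "+"
            right_wants = b.strand == "-"
            if left_wants and right_wants:
                ext_right[i] = min(max_ext, (gap + 1) // 2)
                ext_left[i + 1] = min(max_ext, gap // 2)
            elif left_wants:
                ext_right[i] = min(max_ext, gap)
            elif right_wants:
                ext_left[i + 1] = min(max_ext, gap)
        if genes and genes[0].strand == "-":
            ext_left[0] = min(max_ext, genes[0].start)
        if genes and genes[-1].strand == "+":
            ext_right[-1] = max_ext
        for g, el, er in zip(genes, ext_left, ext_right):
            out.append(GeneBoundary(g.gene_id, chrom, g.strand, g.start - el, g.end + er))
    if overlaps:
        raise ValueError(f"annotated genes overlap: {overlaps}")
    return out


def gene_expression(
    sites: Iterable[PolyASite],
    boundaries: Sequence[GeneBoundary],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Per-gene per-sample counts and RPM, summed over contained same-strand sites.

    Returns a DataFrame indexed by gene_id with ``count_<s>`` / ``rpm_<s>``
    columns.  Sites outside every boundary (or flagged excluded) contribute
    to no gene.
    """
    rows = {
        b.gene_id: {**{f"count_{s}": 0 for s in samples}, **{f"rpm_{s}": 0.0 for s in samples}}
        for b in boundaries
    }
    by_key: dict[tuple[str, str], list[GeneBoundary]] = {}
    for b in boundaries:
        by_key.setdefault((b.chrom, b.strand), []).append(b)
    for bs in by_key.values():
        bs.sort(key=lambda b: b.start)
    for site in sites:
        if site.annotation_category == "mitochondrial":
            continue
        for b in by_key.get((site.chrom, site.strand), ()):  # boundaries never overlap
            if b.contains(site.position):
                row = rows[b.gene_id]
                for s in samples:
                    row[f"count_{s}"] += site.counts.get(s, 0)
                    row[f"rpm_{s}"] += site.rpm.get(s, 0.0)
                break
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def de_test(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    """Two-sided Fisher's exact p on [[count_a, total_a-count_a], [count_b, total_b-count_b]]."""
    if min(count_a, count_b) < 0 or total_a < count_a or total_b < count_b:
        raise ValueError("counts must satisfy 0 <= count <= total")
    return float(fisher_exact([[count_a, total_a - count_a], [count_b, total_b - count_b]])[1])


def call_degs(
    expr: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
    library_sizes: Mapping[str, int],
    fdr_cut: float = 0.01,
    fc_cut: float = 2.0,
    pseudo_rpm: float = 0.1,
    min_total_count: int | None = 10,
) -> pd.DataFrame:
    """Flag differentially expressed genes per pairwise comparison.

    For each comparison (a, b): Fisher's exact p per gene on counts vs
    library totals, BH FDR across the genes tested in that comparison, fold
    change ``(rpm_a + pseudo) / (rpm_b + pseudo)``.  A gene is a DEG iff
    ``fdr < fdr_cut`` and ``max(fc, 1/fc) > fc_cut`` (strict).  Genes whose
    total count over all samples is <= ``min_total_count`` are not tested.
    """
    out = expr.copy()
    count_cols = [c for c in expr.columns if c.startswith("count_")]
    tested = np.ones(len(expr), dtype=bool)
    if min_total_count is not None:
        tested = expr[count_cols].sum(axis=1).to_numpy() > min_total_count
    for a, b in comparisons:
        tag = f"{a}_vs_{b}"
        ca = expr[f"count_{a}"].to_numpy()
        cb = expr[f"count_{b}"].to_numpy()
        pvals = np.full(len(expr), np.nan)
        for i in np.flatnonzero(tested):
            pvals[i] = de_test(int(ca[i]), library_sizes[a], int(cb[i]), library_sizes[b])
        fdr = np.full(len(expr), np.nan)
        if tested.any():
            fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
        fc = (expr[f"rpm_{a}"] + pseudo_rpm) / (expr[f"rpm_{b}"] + pseudo_rpm)
        deg = tested & (fdr < fdr_cut) & (np.maximum(fc, 1 / fc) > fc_cut)
        out[f"p_{tag}"] = pvals
        out[f"fdr_{tag}"] = fdr
        out[f"fc_{tag}"] = fc
        out[f"deg_{tag}"] = deg
        out[f"direction_{tag}"] = np.where(~deg, "none", np.where(fc > 1, "up", "down"))
    return out


def sample_correlation(expr: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2(RPM + 1) across genes (QC helper)."""
    mat = np.log2(expr[[f"rpm_{s}" for s in samples]].to_numpy() + 1.0)
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, j in itertools.combinations(range(len(samples)), 2):
        r = pearsonr(mat[:, i], mat[:, j])[0]
        out.iloc[i, j] = out.iloc[j, i] = r
    return out
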