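"""3'UTR alternative-polyadenylation analysis.

3'UTR isoforms are grouped by shared stop codon; the group region runs from
the stop codon to at most 3,000 nt past the last annotated 3'UTR end,
without entering a neighbouring gene.  Groups whose unextended 3'UTR region
overlaps another gene are discarded.  For each group the two most abundant
poly(A) isoforms define a proximal/distal pair; a two-sided Fisher's exact
test on their read counts between two samples, Bonferroni-corrected over
the groups tested in that comparison, calls usage switches.  A significant
switch requires corrected p < 0.01 and an absolute proximal-usage change
> 5 percentage points.

Isoform "length" is the distance from the stop codon to the poly(A) site in
transcript orientation (for lncRNA gene-wide groups: from the gene 5' end).
The weighted 3'UTR length of a group in a sample is the RPM-weighted mean
distance over all member isoforms; the normalized length divides by the
longest member distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import chi2_contingency, fisher_exact

from apaseq.cluster import PolyASite
from apaseq.io_formats import GeneModel

MAX_EXTENSION_NT = 3000


@dataclass
class UTRIsoform:
    position: int
    distance: int  # nt from stop codon (or lncRNA gene 5' end) to the site
    counts: dict[str, int]
    rpm: dict[str, float]

    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class UTRGroup:
    group_id: str
    gene_id: str
    chrom: str
    strand: str
    stop_pos: int  # half-open boundary between stop codon and 3'UTR
    region: tuple[int, int]
    members: list[UTRIsoform] = field(default_factory=list)
    mode: str = "mRNA_3UTR"  # or lncRNA_genewide


@dataclass
class SwitchResult:
    group_id: str
    proximal_pos: int
    distal_pos: int
    prox_a: int
    dist_a: int
    prox_b: int
    dist_b: int
    usage_a: float
    usage_b: float
    delta_usage: float
    p_raw: float
    p_bonferroni: float
    direction: str  # distal_to_proximal / proximal_to_distal / none
    significant: bool


def _gene_limits(gene_models: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(gene_models, key=lambda m: (m.chrom, m.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    return by_chrom


def group_utrs(
    gene_models: Sequence[GeneModel],
    sites: Iterable[PolyASite],
    max_ext: int = MAX_EXTENSION_NT,
) -> tuple[list[UTRGroup], list[tuple[str, str]]]:
    """Build 3'UTR groups keyed by stop codon and attach member sites.

    Returns (groups, discards); each discard is (group_id, reason).  The
    extension past the last annotated 3'UTR end is capped at ``max_ext`` and
    at the nearest neighbouring gene; a group whose unextended region already
    overlaps another gene is discarded.  lncRNA genes form one gene-wide
    group whose distances are measured from the gene 5' end.
    """
    by_chrom = _gene_limits(gene_models)
    candidates: list[tuple[UTRGroup, tuple[int, int], GeneModel]] = []
    discards: list[tuple[str, str]] = []
    for chrom, genes in by_chrom.items():
        for i, g in enumerate(genes):
            prev_end = genes[i - 1].end if i > 0 else 0
            next_start = genes[i + 1].start if i + 1 < len(genes) else None
            if g.biotype == "coding":
                gid = f"{g.gene_id}:{g.cds_end}"
                if g.strand == "+":
                    base_end = max(g.annotated_utr_ends, default=g.end - 1) + 1
                    cap = next_start if next_start is not None else base_end + max_ext
                    region = (g.cds_end, min(base_end + max_ext, cap))
                    base_region = (g.cds_end, base_end)
                else:
                    base_start = min(g.annotated_utr_ends, default=g.start)
                    region = (max(base_start - max_ext, prev_end), g.cds_end)
                    base_region = (base_start, g.cds_end)
                mode = "mRNA_3UTR"
            else:
                gid = f"{g.gene_id}:genewide"
                region = (g.start, g.end)
                base_region = region
                mode = "lncRNA_genewide"
            grp = UTRGroup(gid, g.gene_id, chrom, g.strand,
                           g.cds_end if g.biotype == "coding" else
                           (g.start if g.strand == "+" else g.end),
                           region, mode=mode)
            candidates.append((grp, base_region, g))
    # discard groups whose unextended 3'UTR overlaps another gene, and any
    # pair of groups whose (extended) regions overlap each other
    dropped: set[str] = set()
    by_chrom_cand: dict[str, list[tuple[UTRGroup, tuple[int, int], GeneModel]]] = {}
    for item in candidates:
        by_chrom_cand.setdefault(item[0].chrom, []).append(item)
    for chrom, items in by_chrom_cand.items():
        for grp, base, g in items:
            for _, _, other in items:
                if other is not g and other.start < base[1] and base[0] < other.end:
                    dropped.add(grp.group_id)
                    discards.append((grp.group_id, f"3'UTR overlaps gene {other.gene_id}"))
                    break
        for (g1, _, m1), (g2, _, m2) in zip(items, items[1:]):
            if m1 is not m2 and g1.region[1] > g2.region[0] and g2.region[1] > g1.region[0]:
                for gid2, other in ((g1.group_id, g2), (g2.group_id, g1)):
                    if gid2 not in dropped:
                        dropped.add(gid2)
                        discards.append((gid2, f"extended region overlaps group {other.group_id}"))
    groups = [grp for grp, _, _ in candidates if grp.group_id not in dropped]
    by_key: dict[tuple[str, str], list[UTRGroup]] = {}
    for grp in groups:
        by_key.setdefault((grp.chrom, grp.strand), []).append(grp)
    for site in sites:
        for grp in by_key.get((site.chrom, site.strand), ()):
            lo, hi = grp.region
            if lo <= site.position < hi:
                grp.members.append(
                    UTRIsoform(site.position, _distance(grp, site.position),
                               dict(site.counts), dict(site.rpm))
                )
    for grp in groups:
        grp.members.sort(key=lambda m: m.distance)
    return groups, discards


def _distance(group: UTRGroup, position: int) -> int:
    """Transcript-orientation distance from the group origin to the site."""
    if group.strand == "+":
        return position - group.stop_pos
    return group.stop_pos - 1 - position


def top_two_isoforms(group: UTRGroup) -> tuple[UTRIsoform, UTRIsoform] | None:
    """The two most abundant member isoforms as a (proximal, distal) pair.

    Abundance is the total read count across samples; ties prefer the
    member closer to the stop codon.  Returns None for groups with fewer
    than two members.
    """
    if len(group.members) < 2:
        return None
    ranked = sorted(group.members, key=lambda m: (-m.total_count(), m.distance))
    a, b = ranked[0], ranked[1]
    return (a, b) if a.distance <= b.distance else (b, a)


def switch_test(
    pair: tuple[UTRIsoform, UTRIsoform],
    sample_a: str,
    sample_b: str,
    n_tests: int = 1,
    group_id: str = "",
    alpha: float = 0.01,
    min_delta: float = 0.05,
) -> SwitchResult | None:
    """Fisher's exact proximal/distal switch test between two samples.

    Returns None when either sample has zero reads on both isoforms (usage
    undefined).  ``direction`` describes sample_a relative to sample_b:
    ``distal_to_proximal`` means proximal usage is higher in sample_a
    (3'UTR shortening in a).
    """
    prox, dist = pair
    pa, da = prox.counts.get(sample_a, 0), dist.counts.get(sample_a, 0)
    pb, db = prox.counts.get(sample_b, 0), dist.counts.get(sample_b, 0)
    if pa + da == 0 or pb + db == 0:
        return None
    p_raw = float(fisher_exact([[pa, da], [pb, db]])[1])
    p_bonf = min(1.0, p_raw * n_tests)
    usage_a = pa / (pa + da)
    usage_b = pb / (pb + db)
    delta = usage_a - usage_b
    # strict ">" with a float guard so a change of exactly min_delta fails
    significant = p_bonf < alpha and abs(delta) - min_delta > 1e-9
    if not significant:
        direction = "none"
    else:
        direction = "distal_to_proximal" if delta > 0 else "proximal_to_distal"
    return SwitchResult(
        group_id=group_id,
        proximal_pos=prox.position,
        distal_pos=dist.position,
        prox_a=pa, dist_a=da, prox_b=pb, dist_b=db,
        usage_a=usage_a, usage_b=usage_b, delta_usage=delta,
        p_raw=p_raw, p_bonferroni=p_bonf,
        direction=direction, significant=significant,
    )


def run_switch_tests(
    groups: Sequence[UTRGroup],
    sample_a: str,
    sample_b: str,
    alpha: float = 0.01,
    min_delta: float = 0.05,
) -> list[SwitchResult]:
    """Run the switch test over every testable group in one pairwise comparison.

    The Bonferroni family size is the number of groups actually tested
    (>= 2 members and nonzero totals in both samples).
    """
    candidates = []
    for grp in groups:
        pair = top_two_isoforms(grp)
        if pair is None:
            continue
        prox, dist = pair
        if (prox.counts.get(sample_a, 0) + dist.counts.get(sample_a, 0) == 0
                or prox.counts.get(sample_b, 0) + dist.counts.get(sample_b, 0) == 0):
            continue
        candidates.append((grp, pair))
    n_tests = len(candidates)
    results = []
    for grp, pair in candidates:
        res = switch_test(pair, sample_a, sample_b, n_tests, grp.group_id, alpha, min_delta)
        if res is not None:
            results.append(res)
    return results


def weighted_utr_length(group: UTRGroup, sample: str) -> float | None:
    """RPM-weighted mean distance over all member isoforms; None if unexpressed."""
    total = sum(m.rpm.get(sample, 0.0) for m in group.members)
    if total <= 0:
        return None
    return sum(m.distance * m.rpm.get(sample, 0.0) for m in group.members) / total


def normalized_utr_length(group: UTRGroup, sample: str) -> float | None:
    """Weighted length normalized by the longest member distance (in (0, 1])."""
    w = weighted_utr_length(group, sample)
    if w is None:
        return None
    longest = max(m.distance for m in group.members)
    if longest <= 0:
        return None
    return w / longest


def summarize_switches(results: Iterable[SwitchResult]) -> dict[str, int]:
    """Tally tested groups into shortened / lengthened / unchanged.

    ``shortened`` counts significant distal-to-proximal switches (sample_a
    uses the proximal site more), ``lengthened`` the reverse.
    """
    out = {"shortened": 0, "lengthened": 0, "unchanged": 0, "tested": 0}
    for r in results:
        out["tested"] += 1
        if r.direction == "distal_to_proximal":
            out["shortened"] += 1
        elif r.direction == "proximal_to_distal":
            out["lengthened"] += 1
        else:
            out["unchanged"] += 1
    return out


def all_sites_chi2(group: UTRGroup, sample_a: str, sample_b: str) -> float | None:
    """Chi-square over the full site-by-sample count table (optional extension).

    This considers every poly(A) site in the group at once rather than the
    top two isoforms; it is off by default in the pipeline and provided only
    as an exploratory alternative to the pairwise Fisher test.
    """
    table = [
        [m.counts.get(sample_a, 0) for m in group.members],
        [m.counts.get(sample_b, 0) for m in group.members],
    ]
    cols = [i for i in range(len(group.members)) if table[0][i] + table[1][i] > 0]
    if len(cols) < 2 or sum(table[0]) == 0 or sum(table[1]) == 0:
        return None
    trimmed = [[row[i] for i in cols] for row in table]
    return float(chi2_contingency(trimmed)[1])
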