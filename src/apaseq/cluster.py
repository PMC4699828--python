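"""Cleavage-position clustering and poly(A)-site calling.

Used reads from all samples are pooled per (chromosome, strand); positions
within 40 nt of each other (single linkage, gap <= 40 inclusive) form raw
clusters.  A raw cluster wider than 40 nt is split greedily: the position
with the highest total RPM seeds a subcluster of everything within +-20 nt,
and the procedure repeats on the remainder until every read is assigned.
The representative position of a cluster (the "poly(A) site") is the member
with the highest summed RPM across samples; clusters below a total-RPM
threshold are dropped.

Two thresholds are shipped as named presets: ``methods5`` (minimum 5 RPM per
cluster) and ``results0.5`` (total RPM > 0.5 across libraries); both appear
in the source study's description of site calling and neither is privileged
here beyond the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from apaseq.io_formats import MappedRead

RPM_PRESETS = {"methods5": 5.0, "results0.5": 0.5}


def compute_rpm(count: int, used_reads_in_sample: int) -> float:
    """Reads-per-million: count per million used reads in the sample."""
    if used_reads_in_sample <= 0:
        raise ValueError("library size (used reads) must be positive")
    return count / used_reads_in_sample * 1e6


@dataclass
class PositionCounts:
    """Per-sample read counts at each cleavage position on one (chrom, strand)."""

    chrom: str
    strand: str
    counts: dict[int, dict[str, int]] = field(default_factory=dict)

    def add(self, position: int, sample: str, n: int = 1) -> None:
        per_sample = self.counts.setdefault(position, {})
        per_sample[sample] = per_sample.get(sample, 0) + n


@dataclass
class SiteCluster:
    chrom: str
    strand: str
    members: dict[int, dict[str, int]]  # position -> per-sample counts

    @property
    def positions(self) -> list[int]:
        return sorted(self.members)

    @property
    def span(self) -> int:
        pos = self.positions
        return pos[-1] - pos[0]

    def total_count(self) -> int:
        return sum(n for per in self.members.values() for n in per.values())

    def sample_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for per in self.members.values():
            for s, n in per.items():
                out[s] = out.get(s, 0) + n
        return out


@dataclass
class PolyASite:
    """A called poly(A) site: representative position plus per-sample expression."""

    site_id: str
    chrom: str
    strand: str
    position: int
    counts: dict[str, int]
    rpm: dict[str, float]
    total_rpm: float
    annotation_category: str | None = None
    host_gene: str | None = None
    novelty_class: str | None = None

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def pool_positions(reads: Iterable[MappedRead]) -> dict[tuple[str, str], PositionCounts]:
    """Pool filtered reads across samples into per-(chrom, strand) position counts."""
    pooled: dict[tuple[str, str], PositionCounts] = {}
    for r in reads:
        key = (r.chrom, r.strand)
        pc = pooled.get(key)
        if pc is None:
            pc = pooled[key] = PositionCounts(r.chrom, r.strand)
        pc.add(r.cleavage_pos, r.sample)
    return pooled


def single_linkage_cluster(pc: PositionCounts, linkage_nt: int = 40) -> list[SiteCluster]:
    """Chain positions with consecutive gaps <= ``linkage_nt`` into raw clusters."""
    clusters: list[SiteCluster] = []
    current: dict[int, dict[str, int]] = {}
    prev = None
    for pos in sorted(pc.counts):
        if prev is not None and pos - prev > linkage_nt:
            clusters.append(SiteCluster(pc.chrom, pc.strand, current))
            current = {}
        current[pos] = dict(pc.counts[pos])
        prev = pos
    if current:
        clusters.append(SiteCluster(pc.chrom, pc.strand, current))
    return clusters


def _position_rpm(per_sample: Mapping[str, int], library_sizes: Mapping[str, int]) -> float:
    return sum(compute_rpm(n, library_sizes[s]) for s, n in per_sample.items())


def _five_prime_first(positions: Iterable[int], strand: str) -> list[int]:
    """Order positions transcript-5' first (ascending on +, descending on -)."""
    return sorted(positions, reverse=(strand == "-"))


def split_cluster(
    cluster: SiteCluster,
    library_sizes: Mapping[str, int],
    max_span: int = 40,
    peak_halfwidth: int = 20,
) -> list[SiteCluster]:
    """Split an over-wide raw cluster at its highest-RPM positions.

    Greedy peak extraction: the unassigned position with the highest summed
    RPM (ties broken toward the transcript-5' side) collects all unassigned
    positions within ``peak_halfwidth`` nt; repeat until no position remains.
    Every read ends up in exactly one subcluster and all subcluster spans are
    <= 2 * peak_halfwidth.
    """
    if cluster.span <= max_span:
        return [cluster]
    unassigned = set(cluster.members)
    out: list[SiteCluster] = []
    while unassigned:
        peak = max(
            _five_prime_first(unassigned, cluster.strand),
            key=lambda p: _position_rpm(cluster.members[p], library_sizes),
        )
        grabbed = {p for p in unassigned if abs(p - peak) <= peak_halfwidth}
        out.append(
            SiteCluster(cluster.chrom, cluster.strand, {p: cluster.members[p] for p in grabbed})
        )
        unassigned -= grabbed
    out.sort(key=lambda c: c.positions[0])
    return out


def call_sites(
    clusters: Iterable[SiteCluster],
    library_sizes: Mapping[str, int],
    min_total_rpm: float = RPM_PRESETS["methods5"],
) -> list[PolyASite]:
    """Pick each cluster's representative position and threshold on total RPM.

    The representative is the member position with the highest RPM summed
    across samples (ties toward the transcript-5' side).  Clusters whose
    total RPM (sum of per-sample RPM over all members) falls below
    ``min_total_rpm`` are dropped.
    """
    if min_total_rpm < 0:
        raise ValueError("min_total_rpm must be >= 0")
    sites: list[PolyASite] = []
    for cluster in clusters:
        rep = max(
            _five_prime_first(cluster.members, cluster.strand),
            key=lambda p: _position_rpm(cluster.members[p], library_sizes),
        )
        counts = cluster.sample_counts()
        rpm = {s: compute_rpm(n, library_sizes[s]) for s, n in counts.items()}
        total = sum(rpm.values())
        if total < min_total_rpm:
            continue
        sites.append(
            PolyASite(
                site_id="",
                chrom=cluster.chrom,
                strand=cluster.strand,
                position=rep,
                counts=counts,
                rpm=rpm,
                total_rpm=total,
            )
        )
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    for i, s in enumerate(sites, 1):
        s.site_id = f"pA{i:06d}"
    return sites


def cluster_and_call(
    reads: Iterable[MappedRead],
    library_sizes: Mapping[str, int],
    linkage_nt: int = 40,
    max_span: int = 40,
    peak_halfwidth: int = 20,
    min_total_rpm: float = RPM_PRESETS["methods5"],
) -> list[PolyASite]:
    """Full site-calling path: pool -> single-linkage -> split -> call."""
    pooled = pool_positions(reads)
    split: list[SiteCluster] = []
    for pc in pooled.values():
        for raw in single_linkage_cluster(pc, linkage_nt):
            split.extend(split_cluster(raw, library_sizes, max_span, peak_halfwidth))
    return call_sites(split, library_sizes, min_total_rpm)
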