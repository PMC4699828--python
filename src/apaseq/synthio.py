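"""Synthetic genomes, gene models and 3'-end reads with full ground truth.

The generator emulates every statistical structure the downstream analysis
assumes: multi-poly(A)-site 3'UTRs, AAUAAA-family PAS hexamers planted
10-40 nt upstream of true cleavage sites, genomic A-rich internal-priming
traps, per-condition proximal/distal usage profiles (including planted
switches), and per-condition expression fold changes.  Reads are emitted
already "mapped" (chromosome / strand / cleavage position records) since
alignment itself is upstream of this pipeline; each carries uniqueness,
mismatch and quality flags so the read-level filters have something to
exercise.

Construction guarantees (asserted by the test suite):

* every planted trap has >= 13 A in the 20-nt transcript-sense window
  ending at the trap position, so the internal-priming filter removes all
  trap reads by construction;
* every true site's corresponding window is capped at <= 12 A (planted PAS
  bases are protected while capping), so no clean true-site read is removed;
* a PAS hexamer (AATAAA or ATTAAA) is planted with probability ``pas_rate``
  with its match start 10-40 nt upstream of the cleavage site.

Cleavage-position jitter is a discretised normal with default sd = 2 nt —
narrow enough that 40-nt single-linkage clustering never splits a true
site, wide enough to exercise it.  Same-strand neighbours are separated by
at least 6,000 nt by default so the 3,000-nt boundary extension is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from apaseq.io_formats import GeneModel, MappedRead
from apaseq.sequence import revcomp

PAS_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass
class SimConfig:
    """Study design for one synthetic dataset.

    ``usage_profiles`` maps each condition to its genome-wide baseline
    proximal-usage fraction; the default 0.7 / 0.5 / 0.3 encodes the
    qualitative pattern that germline stem cells use proximal sites most and
    fibroblasts least.  ``depth`` is the expected number of reads per gene
    per condition (Poisson-drawn); ``de_fold`` and ``switch_usage`` describe
    the planted effects for the ``n_de_genes`` / ``n_switch_genes`` genes
    selected to carry them.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_genes: int = 50
    fraction_lncRNA: float = 0.06
    sites_per_utr: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.4, 3: 0.2}
    )
    pas_rate: float = 0.85
    trap_rate: int = 1
    trap_read_fraction: float = 0.0
    conditions: tuple[str, ...] = ("GSC", "ESC", "MEF")
    usage_profiles: Mapping[str, float] = field(
        default_factory=lambda: {"GSC": 0.7, "ESC": 0.5, "MEF": 0.3}
    )
    n_switch_genes: int = 0
    switch_usage: tuple[float, float] = (0.8, 0.2)
    n_de_genes: int = 0
    de_fold: float = 4.0
    depth: float = 200.0
    position_noise_sd: float = 2.0
    min_gene_gap: int = 6000

    def validate(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.fraction_lncRNA <= 1:
            raise ValueError("fraction_lncRNA must be in [0, 1]")
        if not 0 <= self.pas_rate <= 1:
            raise ValueError("pas_rate must be in [0, 1]")
        if not 0 <= self.trap_read_fraction <= 1:
            raise ValueError("trap_read_fraction must be in [0, 1]")
        for cond in self.conditions:
            u = self.usage_profiles.get(cond)
            if u is None or not 0 <= u <= 1:
                raise ValueError(f"usage profile for {cond!r} missing or outside [0, 1]")
        for u in self.switch_usage:
            if not 0 <= u <= 1:
                raise ValueError("switch_usage fractions must be in [0, 1]")
        if abs(sum(self.sites_per_utr.values()) - 1.0) > 1e-9:
            raise ValueError("sites_per_utr probabilities must sum to 1")


@dataclass
class TrueSite:
    gene_id: str
    chrom: str
    strand: str
    position: int
    distance: int
    usage: dict[str, float]


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset."""

    true_sites: list[TrueSite] = field(default_factory=list)
    switch_genes: list[tuple[str, str]] = field(default_factory=list)
    de_genes: list[tuple[str, float, str]] = field(default_factory=list)
    trap_positions: list[tuple[str, str, str, int]] = field(default_factory=list)

    def sites_of(self, gene_id: str) -> list[TrueSite]:
        return [s for s in self.true_sites if s.gene_id == gene_id]


# ---------------------------------------------------------------------------
# transcript-sense sequence editing helpers

_BASES = np.array(list("ACGT"))


def _write_sense(seq: list[str], strand: str, anchor: int, rel_start: int, motif: str) -> None:
    """Write ``motif`` in transcript sense; rel 0 is the cleavage base at ``anchor``."""
    if strand == "+":
        start = anchor + rel_start
        seq[start : start + len(motif)] = list(motif)
    else:
        end = anchor - rel_start + 1
        seq[end - len(motif) : end] = list(revcomp(motif))


def _read_sense(seq: list[str], strand: str, anchor: int, rel_start: int, length: int) -> str:
    if strand == "+":
        start = anchor + rel_start
        return "".join(seq[start : start + length])
    end = anchor - rel_start + 1
    return revcomp("".join(seq[end - length : end]))


# ---------------------------------------------------------------------------


def make_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Generate a toy genome, gene models and ground truth for one study design.

    Deterministic for a fixed config (including seed).  Raises ``ValueError``
    naming the required minimum chromosome length when the genes do not fit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        c: list(rng.choice(_BASES, size=config.chromosome_length))
        for c in chroms
    }
    truth = TruthTable()
    genes: list[GeneModel] = []

    n_lnc = int(round(config.n_genes * config.fraction_lncRNA))
    site_counts = rng.choice(
        sorted(config.sites_per_utr),
        size=config.n_genes,
        p=[config.sites_per_utr[k] for k in sorted(config.sites_per_utr)],
    )
    biotypes = ["lncRNA"] * n_lnc + ["coding"] * (config.n_genes - n_lnc)
    rng.shuffle(biotypes)

    # planted effects: switches among multi-site genes, DE among all genes
    multi = [i for i in range(config.n_genes) if site_counts[i] >= 2]
    if config.n_switch_genes > len(multi):
        raise ValueError("not enough multi-site genes to plant the requested switches")
    switch_idx = list(rng.choice(multi, size=config.n_switch_genes, replace=False))
    de_idx = list(rng.choice(config.n_genes, size=config.n_de_genes, replace=False))

    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gene_no = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 500
        for _ in range(n_here):
            gid = f"g{gene_no + 1:04d}"
            biotype = biotypes[gene_no]
            n_sites = int(site_counts[gene_no])
            strand = str(rng.choice(["+", "-"]))
            gap = int(rng.integers(config.min_gene_gap, config.min_gene_gap + 2000))

            five_len, cds_len = 100, int(rng.integers(200, 400))
            if biotype == "coding":
                d0 = int(rng.integers(150, 400))
            else:
                d0 = int(rng.integers(300, 700))
            distances = [d0]
            for _k in range(n_sites - 1):
                distances.append(distances[-1] + int(rng.integers(400, 800)))
            utr_span = distances[-1] + 40
            span = (five_len + cds_len if biotype == "coding" else 0) + utr_span

            start = cursor
            end = start + span
            if end > config.chromosome_length - 500:
                need = end + 500
                raise ValueError(
                    f"gene placement failed on {chrom}: chromosome_length must be >= {need}"
                )
            cursor = end + gap

            seq = seqs[chrom]
            if biotype == "coding":
                if strand == "+":
                    cds_start, cds_end = start + five_len, start + five_len + cds_len
                    origin = cds_end  # first 3'UTR base
                    positions = [origin + d for d in distances]
                else:
                    cds_start, cds_end = end - five_len, end - five_len - cds_len
                    origin = cds_end  # half-open boundary; first UTR base is origin-1
                    positions = [origin - 1 - d for d in distances]
            else:
                cds_start = cds_end = None
                if strand == "+":
                    positions = [start + d for d in distances]
                else:
                    positions = [end - 1 - d for d in distances]

            pas_spans: dict[int, tuple[int, int]] = {}
            for pos in positions:
                if rng.random() < config.pas_rate:
                    hexamer = PAS_HEXAMERS[0] if rng.random() < 0.8 else PAS_HEXAMERS[1]
                    rel_start = int(rng.integers(-40, -14))  # match start in [-40, -15]
                    _write_sense(seq, strand, pos, rel_start, hexamer)
                    pas_spans[pos] = (rel_start, rel_start + 6)

            # internal-priming traps inside the transcribed region upstream of
            # the 3'UTR (coding: mid-CDS; lncRNA: before the first site)
            for _t in range(config.trap_rate):
                if biotype == "coding":
                    off = int(rng.integers(30, cds_len - 30))
                    t_pos = (cds_start + off) if strand == "+" else (cds_start - 1 - off)
                else:
                    off = int(rng.integers(40, max(41, distances[0] - 80)))
                    t_pos = (start + off) if strand == "+" else (end - 1 - off)
                window = list("A" * 15) + list(rng.choice(list("CGT"), size=5))
                rng.shuffle(window)
                _write_sense(seq, strand, t_pos, -19, "".join(window))
                truth.trap_positions.append((gid, chrom, strand, t_pos))

            # cap A-content of each true site's upstream window at 12,
            # protecting any planted PAS bases
            for pos in positions:
                protected = set()
                if pos in pas_spans:
                    lo, hi = pas_spans[pos]
                    protected = set(range(lo, hi))
                window = list(_read_sense(seq, strand, pos, -19, 20))
                rel_positions = list(range(-19, 1))
                a_idx = [i for i, b in enumerate(window) if b == "A"]
                free = [i for i in a_idx if rel_positions[i] not in protected]
                excess = len(a_idx) - 12
                for i in free[:max(0, excess)]:
                    window[i] = "C"
                _write_sense(seq, strand, pos, -19, "".join(window))

            # usage profile per condition
            usage: dict[str, float]
            if gene_no in switch_idx and n_sites >= 2:
                direction = (
                    "distal_to_proximal"
                    if switch_idx.index(gene_no) % 2 == 0
                    else "proximal_to_distal"
                )
                hi_u, lo_u = config.switch_usage
                first = config.conditions[0]
                if direction == "distal_to_proximal":
                    usage = {c: (hi_u if c == first else lo_u) for c in config.conditions}
                else:
                    usage = {c: (lo_u if c == first else hi_u) for c in config.conditions}
                truth.switch_genes.append((gid, direction))
            elif n_sites >= 2:
                usage = {c: config.usage_profiles[c] for c in config.conditions}
            else:
                usage = {c: 1.0 for c in config.conditions}

            if gene_no in de_idx:
                de_dir = "up" if de_idx.index(gene_no) % 2 == 0 else "down"
                truth.de_genes.append((gid, config.de_fold, de_dir))

            for pos, dist in sorted(zip(positions, distances), key=lambda x: x[1]):
                truth.true_sites.append(TrueSite(gid, chrom, strand, pos, dist, dict(usage)))

            exons = [(start, end)]
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    annotated_utr_ends=sorted(positions),
                    biotype=biotype,
                )
            )
            gene_no += 1

    genome = {c: "".join(seqs[c]) for c in chroms}
    return genome, genes, truth


def _site_probabilities(sites: list[TrueSite], cond: str) -> np.ndarray:
    """Per-site sampling probabilities: proximal gets its usage fraction,
    the remainder is split evenly over the distal sites."""
    if len(sites) == 1:
        return np.array([1.0])
    u = sites[0].usage[cond]
    rest = (1.0 - u) / (len(sites) - 1)
    return np.array([u] + [rest] * (len(sites) - 1))


def simulate_reads(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: TruthTable,
    config: SimConfig,
) -> dict[str, list[MappedRead]]:
    """Draw per-condition mapped reads from the planted site-usage model.

    Per gene and condition the read total is Poisson(depth x fold); a
    ``trap_read_fraction`` binomial share originates exactly at the gene's
    trap positions, the rest is multinomial over the true sites by usage and
    jittered with a discretised normal of sd ``position_noise_sd``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    for cond in config.conditions:
        if cond not in config.usage_profiles:
            raise KeyError(f"unknown condition label {cond!r}")
    chrom_len = {c: len(s) for c, s in genome.items()}
    fold_map = {gid: (fold, d) for gid, fold, d in truth.de_genes}
    sites_by_gene: dict[str, list[TrueSite]] = {}
    for s in truth.true_sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)
    for sites in sites_by_gene.values():
        sites.sort(key=lambda s: s.distance)
    traps_by_gene: dict[str, list[tuple[str, str, int]]] = {}
    for gid, chrom, strand, pos in truth.trap_positions:
        traps_by_gene.setdefault(gid, []).append((chrom, strand, pos))

    out: dict[str, list[MappedRead]] = {c: [] for c in config.conditions}
    for g in genes:
        sites = sites_by_gene.get(g.gene_id, [])
        if not sites:
            continue
        for cond in config.conditions:
            # planted DE effects apply to the first condition relative to the rest
            if g.gene_id in fold_map and cond == config.conditions[0]:
                fold, de_dir = fold_map[g.gene_id]
                mult = fold if de_dir == "up" else 1.0 / fold
            else:
                mult = 1.0
            lam = config.depth * mult
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            traps = traps_by_gene.get(g.gene_id, [])
            n_trap = (
                int(rng.binomial(n, config.trap_read_fraction))
                if traps and config.trap_read_fraction > 0
                else 0
            )
            if n_trap:
                alloc = rng.multinomial(n_trap, [1 / len(traps)] * len(traps))
                for (chrom, strand, pos), k in zip(traps, alloc):
                    for _ in range(int(k)):
                        out[cond].append(
                            MappedRead(chrom, strand, pos, cond,
                                       n_mismatch=int(rng.integers(0, 2)))
                        )
            n_true = n - n_trap
            probs = _site_probabilities(sites, cond)
            alloc = rng.multinomial(n_true, probs)
            for site, k in zip(sites, alloc):
                k = int(k)
                if k == 0:
                    continue
                if config.position_noise_sd > 0:
                    jitter = np.rint(
                        rng.normal(0.0, config.position_noise_sd, size=k)
                    ).astype(int)
                else:
                    jitter = np.zeros(k, dtype=int)
                hi = chrom_len[site.chrom] - 1
                for j in jitter:
                    pos = min(max(site.position + int(j), 0), hi)
                    out[cond].append(
                        MappedRead(site.chrom, site.strand, pos, cond,
                                   n_mismatch=int(rng.integers(0, 2)))
                    )
    return out


# ---------------------------------------------------------------------------
# truth round-trip

_TRUTH_COLS = [
    "record_type", "gene_id", "chrom", "strand", "position",
    "distance", "direction", "fold", "usage",
]


def export_truth(truth: TruthTable, path: str | Path) -> None:
    """Write the ground truth as one TSV (losslessly round-trips via read_truth)."""
    rows = []
    for s in truth.true_sites:
        usage = ";".join(f"{c}={s.usage[c]:.10g}" for c in s.usage)
        rows.append(["true_site", s.gene_id, s.chrom, s.strand, s.position,
                     s.distance, "", "", usage])
    for gid, direction in truth.switch_genes:
        rows.append(["switch_gene", gid, "", "", "", "", direction, "", ""])
    for gid, fold, direction in truth.de_genes:
        rows.append(["de_gene", gid, "", "", "", "", direction, f"{fold:.10g}", ""])
    for gid, chrom, strand, pos in truth.trap_positions:
        rows.append(["trap", gid, chrom, strand, pos, "", "", "", ""])
    df = pd.DataFrame(rows, columns=_TRUTH_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    truth = TruthTable()
    for _, r in df.iterrows():
        kind = r["record_type"]
        if kind == "true_site":
            usage = {}
            for part in r["usage"].split(";"):
                k, _, v = part.partition("=")
                usage[k] = float(v)
            truth.true_sites.append(
                TrueSite(r["gene_id"], r["chrom"], r["strand"],
                         int(r["position"]), int(r["distance"]), usage)
            )
        elif kind == "switch_gene":
            truth.switch_genes.append((r["gene_id"], r["direction"]))
        elif kind == "de_gene":
            truth.de_genes.append((r["gene_id"], float(r["fold"]), r["direction"]))
        elif kind == "trap":
            truth.trap_positions.append(
                (r["gene_id"], r["chrom"], r["strand"], int(r["position"]))
            )
    return truth


# ---------------------------------------------------------------------------
# gene-model / genome export


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive), including a point
    ``three_prime_utr_end`` feature per annotated 3'UTR terminus."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{ "lncRNA" if g.biotype == "lncRNA" else "protein_coding" }";'
            rows = [("gene", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            if g.biotype == "coding":
                lo, hi = ((g.cds_start, g.cds_end) if g.strand == "+"
                          else (g.cds_end, g.cds_start))
                if g.strand == "+":
                    rows.append(("CDS", lo, hi - 3))
                    rows.append(("stop_codon", hi - 3, hi))
                else:
                    rows.append(("CDS", lo + 3, hi))
                    rows.append(("stop_codon", lo, lo + 3))
            for p in g.annotated_utr_ends:
                rows.append(("three_prime_utr_end", p, p + 1))
            for feature, s, e in rows:
                fh.write(
                    f"{g.chrom}\tapaseq\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            if g.biotype == "coding":
                thick = (g.cds_start, g.cds_end) if g.strand == "+" else (g.cds_end, g.cds_start)
            else:
                thick = (g.start, g.start)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )
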