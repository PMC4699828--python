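"""Parameter-recovery and calibration studies on synthetic data.

Each function here runs one validation experiment against the library's own
implementation — cluster/split agreement with an externally supplied oracle,
internal-priming filter specificity, planted-site recovery, switch-test
power and false-positive rate, 3'UTR length ordering, hexamer recovery, and
DEG recovery — and returns plain dictionaries of rates and counts.  The
oracle-comparison functions take the oracle as a callable so that the
reference implementation stays outside the library.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from apaseq.apa import (
    UTRGroup,
    UTRIsoform,
    group_utrs,
    normalized_utr_length,
    run_switch_tests,
)
from apaseq.cluster import (
    PositionCounts,
    cluster_and_call,
    single_linkage_cluster,
    split_cluster,
)
from apaseq.expression import call_degs
from apaseq.motif import FlankSequence, iterative_hexamer_discovery
from apaseq.preprocess import internal_priming_filter, run_filters
from apaseq.synthio import SimConfig, make_genome, simulate_reads

_ACGT = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# clustering vs oracle


def clustering_oracle_agreement(
    oracle_linkage: Callable[[list[int], int], list[list[int]]],
    oracle_split: Callable[[dict[int, float]], list[list[int]]],
    n_instances: int = 1000,
    max_positions: int = 50,
    seed: int = 0,
) -> dict:
    """Compare single-linkage + peak-splitting against a brute-force oracle.

    Returns the fraction of random instances on which the partition of
    positions matches exactly, plus span/conservation violation counts.
    """
    rng = np.random.default_rng(seed)
    n_match = span_violations = conservation_violations = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_positions + 1))
        positions = sorted(set(rng.integers(0, 500, size=n).tolist()))
        counts = {p: int(rng.integers(1, 30)) for p in positions}
        pc = PositionCounts("chr1", "+")
        for p, c in counts.items():
            pc.add(p, "s", c)
        got: list[list[int]] = []
        total_in = sum(counts.values())
        total_out = 0
        for raw in single_linkage_cluster(pc, 40):
            for sub in split_cluster(raw, {"s": 1_000_000}):
                got.append(sub.positions)
                total_out += sub.total_count()
                if sub.span > 40:
                    span_violations += 1
        if total_out != total_in:
            conservation_violations += 1
        want = [
            grp
            for raw in oracle_linkage(positions, 40)
            for grp in oracle_split({p: float(counts[p]) for p in raw})
        ]
        n_match += sorted(got) == sorted(want)
    return {
        "agreement": n_match / n_instances,
        "span_violations": span_violations,
        "conservation_violations": conservation_violations,
        "n": n_instances,
    }


def fisher_oracle_max_diff(
    oracle: Callable[[int, int, int, int], float],
    n_tables: int = 500,
    max_margin: int = 200,
    seed: int = 0,
) -> dict:
    """Worst absolute difference between the DE/switch p-value and enumeration."""
    from apaseq.expression import de_test

    rng = np.random.default_rng(seed)
    worst = 0.0
    half = max_margin // 2
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, half + 1, size=4))
        if a + b == 0 or c + d == 0:
            continue
        p = de_test(a, a + b, c, c + d)
        worst = max(worst, abs(p - oracle(a, b, c, d)))
    return {"max_abs_diff": worst, "n": n_tables}


# ---------------------------------------------------------------------------
# internal-priming filter


def priming_filter_rates(seed: int = 0, n_genes: int = 50) -> dict:
    """Trap-read removal and clean-read false-removal rates at zero noise."""
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, trap_rate=1, trap_read_fraction=0.1,
        position_noise_sd=0.0,
    )
    genome, genes, truth = make_genome(cfg)
    reads = [r for rr in simulate_reads(genome, genes, truth, cfg).values() for r in rr]
    traps = {(c, s, p) for _, c, s, p in truth.trap_positions}
    trap_reads = [r for r in reads if (r.chrom, r.strand, r.cleavage_pos) in traps]
    clean_reads = [r for r in reads if (r.chrom, r.strand, r.cleavage_pos) not in traps]
    kept_trap, _ = internal_priming_filter(trap_reads, genome)
    kept_clean, _ = internal_priming_filter(clean_reads, genome)
    return {
        "trap_removed": 1.0 - len(kept_trap) / len(trap_reads),
        "clean_removed": 1.0 - len(kept_clean) / len(clean_reads),
        "n_trap_reads": len(trap_reads),
        "n_clean_reads": len(clean_reads),
    }


# ---------------------------------------------------------------------------
# site recovery


def site_recovery(seed: int = 0, n_genes: int = 50, depth: float = 250.0) -> dict:
    """Fraction of planted sites recalled within +-10 nt, and the largest
    distance from any called site to the nearest planted site."""
    cfg = SimConfig(
        seed=seed, n_genes=n_genes, depth=depth, trap_read_fraction=0.05,
        position_noise_sd=2.0,
    )
    genome, genes, truth = make_genome(cfg)
    raw = simulate_reads(genome, genes, truth, cfg)
    used_by = {c: run_filters(rr, genome)[0] for c, rr in raw.items()}
    libs = {c: len(u) for c, u in used_by.items()}
    sites = cluster_and_call([r for u in used_by.values() for r in u], libs,
                             min_total_rpm=5.0)
    truth_by_key: dict[tuple[str, str], np.ndarray] = {}
    for s in truth.true_sites:
        truth_by_key.setdefault((s.chrom, s.strand), []).append(s.position)
    truth_by_key = {k: np.array(sorted(v)) for k, v in truth_by_key.items()}

    def nearest(chrom, strand, pos):
        arr = truth_by_key.get((chrom, strand))
        if arr is None or len(arr) == 0:
            return np.inf
        return int(np.min(np.abs(arr - pos)))

    recovered = 0
    for t in truth.true_sites:
        best = min(
            (abs(s.position - t.position) for s in sites
             if s.chrom == t.chrom and s.strand == t.strand),
            default=np.inf,
        )
        recovered += best <= 10
    max_call_dist = max(
        (nearest(s.chrom, s.strand, s.position) for s in sites), default=0
    )
    return {
        "recovered_within_10nt": recovered / len(truth.true_sites),
        "max_called_to_truth_nt": float(max_call_dist),
        "n_true_sites": len(truth.true_sites),
        "n_called_sites": len(sites),
    }


# ---------------------------------------------------------------------------
# switch power / FPR


def _binomial_group(rng, gid, u_a, u_b, n_reads) -> UTRGroup:
    pa = int(rng.binomial(n_reads, u_a))
    pb = int(rng.binomial(n_reads, u_b))
    prox = UTRIsoform(1000, 200, {"a": pa, "b": pb}, {"a": float(pa), "b": float(pb)})
    dist = UTRIsoform(1800, 1000, {"a": n_reads - pa, "b": n_reads - pb},
                      {"a": float(n_reads - pa), "b": float(n_reads - pb)})
    return UTRGroup(gid, gid, "chr1", "+", 800, (800, 4000), [prox, dist])


def switch_power_fpr(
    n_seeds: int = 100,
    n_switch: int = 100,
    n_null: int = 100,
    reads_per_sample: int = 200,
    switch_usage: tuple[float, float] = (0.8, 0.2),
    null_usage: float = 0.5,
    seed: int = 0,
) -> dict:
    """Power and false-positive rate of the proximal/distal switch test.

    Per seed, ``n_switch`` groups with planted usage ``switch_usage[0]`` in
    sample a vs ``switch_usage[1]`` in sample b, plus ``n_null`` groups with
    identical usage, each with ``reads_per_sample`` reads; the Bonferroni
    family is all groups tested in the comparison.
    """
    ss = np.random.SeedSequence([seed, 101])
    hits = false = 0
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        groups = [
            _binomial_group(rng, f"sw{i}", switch_usage[0], switch_usage[1],
                            reads_per_sample)
            for i in range(n_switch)
        ] + [
            _binomial_group(rng, f"null{i}", null_usage, null_usage, reads_per_sample)
            for i in range(n_null)
        ]
        results = {r.group_id: r for r in run_switch_tests(groups, "a", "b")}
        for i in range(n_switch):
            r = results.get(f"sw{i}")
            hits += bool(r and r.significant and r.direction == "distal_to_proximal")
        for i in range(n_null):
            r = results.get(f"null{i}")
            false += bool(r and r.significant)
    return {
        "power": hits / (n_seeds * n_switch),
        "fpr": false / (n_seeds * n_null),
        "n": n_seeds * (n_switch + n_null),
    }


# ---------------------------------------------------------------------------
# global 3'UTR length ordering


def length_ordering(seed: int = 0, n_genes: int = 60, depth: float = 250.0) -> dict:
    """Mean normalized 3'UTR length per condition under the default
    genome-wide proximal-usage gradient (0.7 / 0.5 / 0.3)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, depth=depth)
    genome, genes, truth = make_genome(cfg)
    raw = simulate_reads(genome, genes, truth, cfg)
    used_by = {c: run_filters(rr, genome)[0] for c, rr in raw.items()}
    libs = {c: len(u) for c, u in used_by.items()}
    sites = cluster_and_call([r for u in used_by.values() for r in u], libs,
                             min_total_rpm=5.0)
    groups, _ = group_utrs(genes, sites)
    means = {}
    for cond in cfg.conditions:
        vals = [
            v for g in groups if len(g.members) >= 2
            if (v := normalized_utr_length(g, cond)) is not None
        ]
        means[f"mean_normalized_{cond}"] = float(np.mean(vals))
    means["strictly_ordered"] = (
        means["mean_normalized_GSC"]
        < means["mean_normalized_ESC"]
        < means["mean_normalized_MEF"]
    )
    return means


# ---------------------------------------------------------------------------
# hexamer recovery


def _random_flanks(rng, n: int, length: int = 200) -> list[FlankSequence]:
    block = rng.choice(_ACGT, size=(n, length))
    return [FlankSequence(f"f{i}", "".join(row), length // 2) for i, row in enumerate(block)]


def hexamer_recovery(
    n_seeds: int = 100,
    n_flanks: int = 2000,
    primary_rate: float = 0.6,
    secondary_rate: float = 0.2,
    seed: int = 0,
) -> dict:
    """Rank-1/2 recovery of AATAAA/ATTAAA planted in disjoint flank subsets,
    and the false-motif emission rate on matched null (uniform) flank sets."""
    ss = np.random.SeedSequence([seed, 202])
    n_ok = 0
    null_emissions = 0
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        flanks = _random_flanks(rng, n_flanks)
        n1 = int(primary_rate * n_flanks)
        n2 = int(secondary_rate * n_flanks)
        planted = []
        for i, f in enumerate(flanks):
            if i < n1:
                motif, rel = "AATAAA", -25
            elif i < n1 + n2:
                motif, rel = "ATTAAA", -30
            else:
                planted.append(f)
                continue
            j = f.offset + rel
            planted.append(FlankSequence(
                f.site_id, f.sequence[:j] + motif + f.sequence[j + 6:], f.offset
            ))
        results = iterative_hexamer_discovery(planted)
        top2 = [r.hexamer for r in results[:2]]
        n_ok += top2 == ["AATAAA", "ATTAAA"]
        null_results = iterative_hexamer_discovery(_random_flanks(rng, n_flanks))
        null_emissions += len(null_results)
    return {
        "rank12_recovery": n_ok / n_seeds,
        "null_emission_rate": null_emissions / n_seeds,
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# DEG recovery


def deg_power_fpr(
    n_seeds: int = 100,
    n_de: int = 10,
    n_null: int = 90,
    depth: float = 500.0,
    fold: float = 4.0,
    seed: int = 0,
) -> dict:
    """Recovery of planted fold changes and null flag rate for the
    Fisher/BH differential-expression call at depth ``depth``."""
    ss = np.random.SeedSequence([seed, 303])
    hits = false = 0
    background = 200_000  # used reads outside the simulated genes
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        lam_a = np.full(n_de + n_null, depth)
        lam_a[:n_de // 2] *= fold
        lam_a[n_de // 2 : n_de] /= fold
        counts_a = rng.poisson(lam_a)
        counts_b = rng.poisson(np.full(n_de + n_null, depth))
        lib_a = int(counts_a.sum()) + background
        lib_b = int(counts_b.sum()) + background
        df = pd.DataFrame({
            "count_a": counts_a,
            "count_b": counts_b,
            "rpm_a": counts_a / lib_a * 1e6,
            "rpm_b": counts_b / lib_b * 1e6,
        }, index=[f"g{i}" for i in range(n_de + n_null)])
        out = call_degs(df, [("a", "b")], {"a": lib_a, "b": lib_b})
        flags = out["deg_a_vs_b"].to_numpy()
        hits += int(flags[:n_de].sum())
        false += int(flags[n_de:].sum())
    return {
        "power": hits / (n_seeds * n_de),
        "fpr": false / (n_seeds * n_null),
        "n": n_seeds * (n_de + n_null),
    }
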