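"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithms/data structures than the library
(union-find over all pairs instead of a sorted sweep; direct hypergeometric
enumeration instead of scipy's Fisher routine) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def brute_force_single_linkage(positions: list[int], linkage_nt: int = 40) -> list[list[int]]:
    """Union-find transitive closure over all position pairs."""
    pos = sorted(set(positions))
    parent = list(range(len(pos)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if abs(pos[i] - pos[j]) <= linkage_nt:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def brute_force_split(
    members: dict[int, float], max_span: int = 40, peak_halfwidth: int = 20,
    strand: str = "+",
) -> list[list[int]]:
    """Step-by-step greedy peak splitting on {position: rpm} weights.

    Returns the member-position partition; a cluster within ``max_span`` is
    returned whole.  Ties on weight go to the transcript-5' position.
    """
    pos = sorted(members)
    if pos[-1] - pos[0] <= max_span:
        return [pos]
    out = []
    left = dict(members)
    while left:
        best_w = max(left.values())
        candidates = [p for p, w in left.items() if w == best_w]
        peak = min(candidates) if strand == "+" else max(candidates)
        sub = [p for p in left if peak - peak_halfwidth <= p <= peak + peak_halfwidth]
        out.append(sorted(sub))
        for p in sub:
            del left[p]
    return sorted(out, key=lambda g: g[0])


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p-value.

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed the observed one (with the standard
    1e-7 relative tolerance for ties).
    """
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (n_total - row1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(ks, n_total, row1, col1)
    p_obs = hypergeom.pmf(a, n_total, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def bh_ladder(pvals: list[float]) -> list[float]:
    """Hand-rolled Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
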