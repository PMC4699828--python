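"""PAS hexamer discovery around poly(A) sites.

Flanking sequences (default +-100 nt, transcript strand) are scanned for
6-mers.  The expected number of flanks containing each hexamer is computed
from the pooled mononucleotide composition of the flanks: with per-window
probability p (product of base frequencies) and W windows per flank, the
containment probability is 1 - (1 - p)^W.  Discovery is iterative: the
hexamer with the most significant one-sided binomial excess of containing
flanks (Bonferroni over all 4^6 hexamers) is emitted, every flank
containing it is removed, the background is re-estimated, and the search
repeats until ten motifs are found or nothing passes the significance
cutoff.  Containment is per flank (presence/absence), matching the removal
rule.

Internally sequences are DNA; reported motifs carry an RNA rendering
(AATAAA -> AAUAAA) for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from apaseq.sequence import chrom_length, fetch, revcomp

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


@dataclass
class FlankSequence:
    """Transcript-strand sequence around one cleavage site.

    ``offset`` is the index of the cleavage base within ``sequence``
    (relative position 0); relative position -j is j nt upstream.
    ``trunc_left``/``trunc_right`` record bases lost to contig ends.
    """

    site_id: str
    sequence: str
    offset: int
    trunc_left: int = 0
    trunc_right: int = 0


@dataclass
class HexamerResult:
    hexamer: str
    rna: str
    observed: int
    expected: float
    p_value: float
    rank: int
    iteration: int


def extract_flanks(
    sites: Sequence,
    genome,
    upstream: int = 100,
    downstream: int = 100,
) -> list[FlankSequence]:
    """Extract transcript-strand flanks around each site's cleavage position.

    On the plus strand the window is genomic ``[p - upstream, p + downstream)``;
    minus-strand windows are mirrored and reverse-complemented so that the
    flank always reads 5'->3' with the cleavage base at relative position 0.
    """
    out = []
    for s in sites:
        p = s.position
        if s.strand == "+":
            start, end = p - upstream, p + downstream
            seq = fetch(genome, s.chrom, start, end)
            trunc_left = max(0, -start)
            trunc_right = max(0, end - chrom_length(genome, s.chrom))
        else:
            start, end = p - downstream + 1, p + upstream + 1
            raw = fetch(genome, s.chrom, start, end)
            seq = revcomp(raw)
            trunc_left = max(0, end - chrom_length(genome, s.chrom))
            trunc_right = max(0, -start)
        out.append(
            FlankSequence(s.site_id, seq, upstream - trunc_left, trunc_left, trunc_right)
        )
    return out


# ---------------------------------------------------------------------------
# k-mer machinery


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-window (code -1 where a window contains non-ACGT)."""
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        bad |= c < 0
        out = out * 4 + np.where(c < 0, 0, c)
    out[bad] = -1
    return out


def decode_kmer(code: int, k: int = 6) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = code * 4 + "ACGT".index(b)
    return code


def _presence_matrix(flanks: Sequence[FlankSequence], k: int) -> list[np.ndarray]:
    """Per flank, the sorted unique codes of contained k-mers."""
    return [
        np.unique(c[c >= 0]) for c in (_window_codes(f.sequence, k) for f in flanks)
    ]


def background_expectation(
    flanks: Sequence[FlankSequence], k: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Expected containing-flank count per k-mer under pooled base composition.

    Returns ``(expected_counts, p_contain)`` arrays of length 4^k, where
    ``p_contain`` is the mean per-flank containment probability.
    """
    if not flanks:
        raise ValueError("no flanks to estimate background from")
    base_counts = np.zeros(4, dtype=np.int64)
    lengths = []
    for f in flanks:
        codes = _encode(f.sequence)
        base_counts += np.bincount(codes[codes >= 0], minlength=4)
        lengths.append(len(f.sequence))
    total = base_counts.sum()
    if total == 0:
        raise ValueError("flanks contain no ACGT bases")
    freqs = base_counts / total
    n_kmers = 4**k
    digits = np.stack(
        [np.arange(n_kmers) // (4**j) % 4 for j in range(k)], axis=0
    )
    p_window = np.prod(freqs[digits], axis=0)
    windows = np.array([max(0, L - k + 1) for L in lengths])
    # sum over flanks of 1-(1-p)^W, grouped by flank length
    expected = np.zeros(n_kmers)
    for w, mult in zip(*np.unique(windows, return_counts=True)):
        if w > 0:
            expected += mult * (1.0 - np.power(1.0 - p_window, w))
    p_contain = expected / len(flanks)
    return expected, p_contain


def iterative_hexamer_discovery(
    flanks: Sequence[FlankSequence],
    k: int = 6,
    top_n: int = 10,
    alpha: float = 0.01,
) -> list[HexamerResult]:
    """Select-and-remove discovery of enriched hexamers.

    Each iteration: one-sided binomial p-value (observed vs expected
    containing-flank counts) per hexamer, Bonferroni over 4^k; the most
    significant hexamer is emitted and all flanks containing it removed.
    Stops at ``top_n`` motifs or when no hexamer passes ``alpha``.
    """
    if not flanks:
        raise ValueError("no flanks given")
    n_kmers = 4**k
    presence = _presence_matrix(flanks, k)
    remaining = list(range(len(flanks)))
    results: list[HexamerResult] = []
    for iteration in range(1, top_n + 1):
        if not remaining:
            break
        sub = [flanks[i] for i in remaining]
        expected, p_contain = background_expectation(sub, k)
        observed = np.zeros(n_kmers, dtype=np.int64)
        for i in remaining:
            observed += np.bincount(presence[i], minlength=n_kmers)
        n = len(remaining)
        pvals = binom.sf(observed - 1, n, np.clip(p_contain, 0.0, 1.0))
        pvals_bonf = np.minimum(1.0, pvals * n_kmers)
        best = int(np.argmin(pvals))
        if pvals_bonf[best] >= alpha or observed[best] == 0:
            break
        hexamer = decode_kmer(best, k)
        results.append(
            HexamerResult(
                hexamer=hexamer,
                rna=hexamer.replace("T", "U"),
                observed=int(observed[best]),
                expected=float(expected[best]),
                p_value=float(pvals_bonf[best]),
                rank=iteration,
                iteration=iteration,
            )
        )
        remaining = [i for i in remaining if best not in presence[i]]
    return results


def pas_presence(
    flanks: Sequence[FlankSequence],
    motifs: Iterable[str],
    window: tuple[int, int] = (-40, -10),
) -> float:
    """Fraction of sites with any motif match starting inside ``window``.

    ``window`` is in relative coordinates (cleavage base = 0); only flanks
    whose window is fully available (no truncation into it) are counted in
    the denominator.
    """
    motifs = list(motifs)
    if not motifs:
        raise ValueError("no motifs given")
    lo, hi = window
    k = len(motifs[0])
    codes = {kmer_code(m) for m in motifs}
    n_eval = n_hit = 0
    for f in flanks:
        start = f.offset + lo
        end = f.offset + hi + 1  # last allowed match START is at rel hi
        if start < 0 or end + k - 1 > len(f.sequence):
            continue
        n_eval += 1
        wc = _window_codes(f.sequence[start : end + k - 1], k)
        if np.isin(wc, list(codes)).any():
            n_hit += 1
    if n_eval == 0:
        return float("nan")
    return n_hit / n_eval


def subregion_partition(
    sites: Sequence,
    genome,
    out_prefix: str | Path,
    flank: int = 500,
    n_regions: int = 5,
) -> tuple[list[Path], int]:
    """Split the +-``flank`` span around each site into equal subregions and
    export one FASTA per subregion (input for external motif tools).

    Sites whose span is truncated by a contig end are excluded; the count of
    exclusions is returned alongside the written paths.
    """
    if (2 * flank) % n_regions:
        raise ValueError("2*flank must divide evenly into n_regions")
    size = 2 * flank // n_regions
    flanks = extract_flanks(sites, genome, upstream=flank, downstream=flank)
    n_excluded = 0
    paths = [Path(f"{out_prefix}{i + 1}.fa") for i in range(n_regions)]
    handles = [open(p, "w") for p in paths]
    try:
        for f in flanks:
            if f.trunc_left or f.trunc_right or len(f.sequence) != 2 * flank:
                n_excluded += 1
                continue
            for i, fh in enumerate(handles):
                sub = f.sequence[i * size : (i + 1) * size]
                lo = -flank + i * size
                fh.write(f">{f.site_id}|{lo}..{lo + size}\n{sub}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths, n_excluded
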