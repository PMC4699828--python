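"""Read-level filters applied before poly(A)-site clustering.

Two stages: (1) alignment quality — keep uniquely aligned reads with at most
one mismatch and acceptable base quality; (2) internal-priming removal —
discard reads whose cleavage site sits next to a genomic A-rich tract
(more than 12 A in a 20-nt window), the signature of oligo-dT priming on
internal adenosine runs rather than on a real poly(A) tail.  Reads surviving
both stages are the "used reads" that define library sizes for RPM.

The A-rich window can be taken on either side of the poly(A) junction.  The
default, ``upstream``, interrogates the 20 transcribed bases ending at the
cleavage position (the read's own 3' terminus); ``downstream`` interrogates
the 20 genomic bases immediately past the junction, which is how most
internal-priming filters in the field are oriented.  Both are exposed
because the biology motivates either choice and the artifact tract often
spans the junction anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from apaseq.io_formats import MappedRead
from apaseq.sequence import fetch


@dataclass
class FilterReport:
    """Read counts surviving each filter stage (monotone non-increasing)."""

    n_input: int = 0
    n_after_quality: int = 0
    n_after_unique: int = 0
    n_after_internal_priming: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_after_quality": self.n_after_quality,
            "n_after_unique": self.n_after_unique,
            "n_after_internal_priming": self.n_after_internal_priming,
        }


def filter_alignment_quality(
    reads: Iterable[MappedRead], max_mismatch: int = 1
) -> tuple[list[MappedRead], FilterReport]:
    """Retain reads that are quality-ok, uniquely aligned and have <= 1 mismatch."""
    report = FilterReport()
    kept: list[MappedRead] = []
    for r in reads:
        report.n_input += 1
        if not r.quality_ok:
            continue
        report.n_after_quality += 1
        if not (r.is_unique and r.n_mismatch <= max_mismatch):
            continue
        report.n_after_unique += 1
        kept.append(r)
    return kept, report


def priming_window(read: MappedRead, window_nt: int = 20, side: str = "upstream") -> tuple[int, int]:
    """Genomic [start, end) of the A-content window for one read.

    Coordinates are un-clamped; callers truncate at chromosome bounds.
    """
    p = read.cleavage_pos
    if side == "upstream":
        # last `window_nt` transcribed bases, cleavage base included
        return (p - window_nt + 1, p + 1) if read.strand == "+" else (p, p + window_nt)
    if side == "downstream":
        return (p + 1, p + window_nt + 1) if read.strand == "+" else (p - window_nt, p)
    raise ValueError(f"window side must be 'upstream' or 'downstream', got {side!r}")


def internal_priming_filter(
    reads: Iterable[MappedRead],
    genome,
    window_nt: int = 20,
    max_a: int = 12,
    window_side: str = "upstream",
) -> tuple[list[MappedRead], int]:
    """Discard reads with > ``max_a`` adenosines in the window next to the cleavage site.

    A counting is on the transcript strand: minus-strand windows count 'T' on
    the reference.  Windows truncated at chromosome ends are evaluated on the
    available bases against the same absolute threshold.  Returns the retained
    reads and the number discarded.
    """
    kept: list[MappedRead] = []
    n_discarded = 0
    for r in reads:
        start, end = priming_window(r, window_nt, window_side)
        seq = fetch(genome, r.chrom, start, end)
        n_a = seq.count("A") if r.strand == "+" else seq.count("T")
        if n_a > max_a:
            n_discarded += 1
        else:
            kept.append(r)
    return kept, n_discarded


def run_filters(
    reads: Iterable[MappedRead],
    genome,
    window_nt: int = 20,
    max_a: int = 12,
    window_side: str = "upstream",
) -> tuple[list[MappedRead], FilterReport]:
    """Both filter stages in order; returns used reads and the full report."""
    kept, report = filter_alignment_quality(reads)
    used, _ = internal_priming_filter(kept, genome, window_nt, max_a, window_side)
    report.n_after_internal_priming = len(used)
    return used, report
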