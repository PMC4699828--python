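"""Genome sequence access shared by the filtering and motif modules.

A "genome" is either a plain ``{chrom: sequence}`` mapping (what the
simulator produces in memory) or a :class:`pyfaidx.Fasta` opened with
``as_raw=True``; both support the same slicing and ``len`` protocol used
here.
"""

from __future__ import annotations

from pathlib import Path

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def load_genome(path: str | Path):
    """Open a FASTA for random access (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def chrom_length(genome, chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    return len(genome[chrom])


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) clamped to chromosome bounds, uppercase."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    n = len(genome[chrom])
    start, end = max(0, start), min(n, end)
    if end <= start:
        return ""
    return str(genome[chrom][start:end]).upper()


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
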