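"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention).  GTF input
(1-based, fully closed) is converted at the boundary.  The one subtle
convention is ``cds_end``: it is stored as the half-open boundary between the
stop codon and the 3'UTR in transcript orientation, i.e. for a plus-strand
gene the 0-based coordinate one past the last stop-codon base, and for a
minus-strand gene the numerically smallest stop-codon coordinate.  With that
convention the plus-strand 3'UTR is simply ``[cds_end, exon_end)`` and the
minus-strand 3'UTR is ``[exon_start, cds_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd


class FormatError(ValueError):
    """A file did not parse as the declared format."""


@dataclass
class GeneModel:
    """One gene locus with exon structure and 3'-end annotation.

    ``annotated_utr_ends`` holds the genomic positions of annotated 3'UTR
    termini (one per annotated isoform); they drive the known/novel
    classification of called poly(A) sites.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    annotated_utr_ends: list[int] = field(default_factory=list)
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        if self.biotype == "coding" and self.cds_end is None:
            raise ValueError(f"coding gene {self.gene_id} lacks cds_end")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def three_prime_end(self) -> int:
        """Transcript-orientation 3' terminus (half-open boundary)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class MappedRead:
    """One aligned 3'-terminal read.

    ``cleavage_pos`` is the genomic position of the last transcribed
    nucleotide (the base 5' of the poly(A) junction).
    """

    chrom: str
    strand: str
    cleavage_pos: int
    sample: str
    is_unique: bool = True
    n_mismatch: int = 0
    quality_ok: bool = True


# ---------------------------------------------------------------------------
# gene models


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_models(path: str | Path, fmt: str = "GTF") -> list[GeneModel]:
    """Read gene models from a GTF or BED12 file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    A coding gene in GTF must carry CDS (and optionally stop_codon) features;
    the stop codon is treated as part of the coding span so the 3'UTR begins
    immediately after it.
    """
    fmt = fmt.upper()
    if fmt == "GTF":
        return _read_gtf(Path(path))
    if fmt == "BED12":
        return _read_bed12(Path(path))
    raise ValueError(f"unknown gene-model format {fmt!r}")


def _read_gtf(path: Path) -> list[GeneModel]:
    # accumulate per gene_id
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            try:
                start_i, end_i = int(start) - 1, int(end)  # -> 0-based half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            a = _parse_gtf_attrs(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            g = genes.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "exons": [], "cds": [],
                 "stop": [], "utr_ends": [], "biotype": a.get("gene_biotype", "coding")},
            )
            if a.get("gene_biotype"):
                g["biotype"] = a["gene_biotype"]
            if feature == "exon":
                g["exons"].append((start_i, end_i))
            elif feature == "CDS":
                g["cds"].append((start_i, end_i))
            elif feature == "stop_codon":
                g["stop"].append((start_i, end_i))
            elif feature == "three_prime_utr_end":
                # custom point feature written by the simulator
                g["utr_ends"].append(start_i)
    out = []
    for gid, g in genes.items():
        biotype = "lncRNA" if g["biotype"] in ("lncRNA", "lincRNA", "non_coding") else "coding"
        cds_start = cds_end = None
        if biotype == "coding":
            if not g["cds"]:
                import warnings

                warnings.warn(f"coding gene {gid} lacks CDS features; skipped")
                continue
            coding = sorted(g["cds"] + g["stop"])
            if g["strand"] == "+":
                cds_start = coding[0][0]
                cds_end = coding[-1][1]
            else:
                cds_start = coding[-1][1]
                cds_end = coding[0][0]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                exons=_merge_adjacent(sorted(g["exons"])),
                cds_start=cds_start,
                cds_end=cds_end,
                annotated_utr_ends=sorted(g["utr_ends"]),
                biotype=biotype,
            )
        )
    out.sort(key=lambda m: (m.chrom, m.start))
    return out


def _merge_adjacent(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in exons:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _read_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, _end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            coding = thick_end > thick_start
            out.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=(thick_start if strand == "+" else thick_end) if coding else None,
                    cds_end=(thick_end if strand == "+" else thick_start) if coding else None,
                    biotype="coding" if coding else "lncRNA",
                )
            )
    out.sort(key=lambda m: (m.chrom, m.start))
    return out


# ---------------------------------------------------------------------------
# mapped reads


def read_mapped_reads(path: str | Path, fmt: str = "BED6") -> Iterator[MappedRead]:
    """Stream mapped 3'-end reads from BED6 or SAM/BAM.

    The cleavage position is the strand-aware transcript 3' terminus of the
    alignment: ``end - 1`` on the plus strand, ``start`` on the minus strand.
    Sample identity comes from the ``sample:`` prefix of the BED name field,
    or from the SAM read group (falling back to the same name prefix).
    """
    fmt = fmt.upper()
    if fmt == "BED6":
        yield from _read_bed6(Path(path))
    elif fmt in ("SAM", "BAM"):
        yield from _read_sam(Path(path))
    else:
        raise ValueError(f"unknown read format {fmt!r}")


def _read_bed6(path: Path) -> Iterator[MappedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[:6]
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unstranded record rejected")
            start_i, end_i = int(start), int(end)
            sample = name.split(":", 1)[0]
            cleavage = end_i - 1 if strand == "+" else start_i
            yield MappedRead(chrom, strand, cleavage, sample)


def _read_sam(path: Path) -> Iterator[MappedRead]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        rg_sample = {rg["ID"]: rg.get("SM", rg["ID"]) for rg in fh.header.get("RG", [])}
        for aln in fh:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            cleavage = aln.reference_start if strand == "-" else aln.reference_end - 1
            if aln.has_tag("RG"):
                sample = rg_sample.get(aln.get_tag("RG"), str(aln.get_tag("RG")))
            else:
                sample = aln.query_name.split(":", 1)[0]
            nm = int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
            unique = not (aln.is_secondary or aln.is_supplementary)
            if aln.has_tag("NH"):
                unique = unique and int(aln.get_tag("NH")) == 1
            yield MappedRead(
                chrom=aln.reference_name,
                strand=strand,
                cleavage_pos=cleavage,
                sample=sample,
                is_unique=unique,
                n_mismatch=nm,
                quality_ok=not aln.is_qcfail,
            )


def write_reads_bed(reads: Iterable[MappedRead], path: str | Path, read_len: int = 50,
                    mapq: int = 42) -> None:
    """Write reads as 6-column BED with ``sample:readID`` names.

    The record spans the last ``read_len`` transcribed bases ending at the
    cleavage position, so re-reading recovers the cleavage position exactly.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            if r.strand == "+":
                start, end = max(0, r.cleavage_pos - read_len + 1), r.cleavage_pos + 1
            else:
                start, end = r.cleavage_pos, r.cleavage_pos + read_len
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.sample}:r{i}\t{mapq}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# sites and tables


def write_sites_bed(sites: Sequence, path: str | Path) -> None:
    """Write called poly(A) sites as BED6 (score = total RPM x 100, rounded)."""
    rows = sorted(sites, key=lambda s: (s.chrom, s.position))
    with open(path, "w") as fh:
        for s in rows:
            score = int(round(s.total_rpm * 100))
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.site_id}\t{score}\t{s.strand}\n")


def read_sites_bed(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a sites BED back as (chrom, position, strand, site_id) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), f[5], f[3]))
    return out


def write_table(records: pd.DataFrame | Iterable[dict], path: str | Path) -> None:
    """Write records as TSV with header; floats at 6 significant digits."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
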