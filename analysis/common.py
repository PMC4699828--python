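"""Shared study definition for the numbered analysis scripts.

The study emulates the three-cell-type design (GSC / ESC / MEF): 50 genes,
a genome-wide proximal-usage gradient 0.7 / 0.5 / 0.3, five planted 3'UTR
switch genes, five planted 4-fold expression changes, one internal-priming
trap per gene carrying 5% of reads, and 2-nt cleavage jitter.  Bulky
artefacts (FASTA, BED) live under scratch/study; small result tables under
results/.
"""

from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_SEED = 2026

def study_config():
    from apaseq.synthio import SimConfig

    return SimConfig(
        seed=STUDY_SEED,
        n_genes=50,
        depth=250.0,
        trap_read_fraction=0.05,
        n_switch_genes=5,
        n_de_genes=5,
    )


def load_or_build():
    """Deterministically (re)build the study in memory; write scratch files once."""
    from apaseq.io_formats import write_reads_bed
    from apaseq.sequence import write_fasta
    from apaseq.synthio import export_truth, make_genome, simulate_reads, write_gtf

    cfg = study_config()
    genome, genes, truth = make_genome(cfg)
    reads = simulate_reads(genome, genes, truth, cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    if not (SCRATCH / "genome.fa").exists():
        write_fasta(genome, SCRATCH / "genome.fa")
        write_gtf(genes, SCRATCH / "genes.gtf")
        for cond, rr in reads.items():
            write_reads_bed(rr, SCRATCH / f"reads_{cond}.bed")
        export_truth(truth, SCRATCH / "truth.tsv")
    return cfg, genome, genes, truth, reads


def used_reads():
    """Filtered ('used') reads and library sizes for the study."""
    from apaseq.preprocess import run_filters

    cfg, genome, genes, truth, reads = load_or_build()
    used_by, reports = {}, {}
    for cond, rr in reads.items():
        used, rep = run_filters(rr, genome)
        used_by[cond] = used
        reports[cond] = rep
    libs = {c: len(u) for c, u in used_by.items()}
    return cfg, genome, genes, truth, used_by, libs, reports


def called_sites():
    from apaseq.cluster import cluster_and_call

    cfg, genome, genes, truth, used_by, libs, _ = used_reads()
    sites = cluster_and_call(
        [r for u in used_by.values() for r in u], libs, min_total_rpm=5.0
    )
    return cfg, genome, genes, truth, sites, libs
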