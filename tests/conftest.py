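from __future__ import annotations

import pytest

from apaseq.cluster import cluster_and_call
from apaseq.preprocess import run_filters
from apaseq.synthio import SimConfig, make_genome, simulate_reads


@pytest.fixture(scope="session")
def study():
    """One mid-sized synthetic study shared across test modules.

    50 genes on two chromosomes, three conditions with the default
    proximal-usage gradient, planted switches, DE genes and one
    internal-priming trap per gene.
    """
    cfg = SimConfig(
        seed=11,
        n_genes=50,
        depth=300.0,
        trap_read_fraction=0.05,
        n_switch_genes=5,
        n_de_genes=5,
    )
    genome, genes, truth = make_genome(cfg)
    reads = simulate_reads(genome, genes, truth, cfg)
    used_by = {}
    for cond, rr in reads.items():
        used, _ = run_filters(rr, genome)
        used_by[cond] = used
    library_sizes = {c: len(u) for c, u in used_by.items()}
    sites = cluster_and_call(
        [r for u in used_by.values() for r in u], library_sizes, min_total_rpm=5.0
    )
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "reads": reads,
        "used_by": used_by,
        "library_sizes": library_sizes,
        "sites": sites,
    }
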