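"""End-to-end orchestration: filter -> cluster -> annotate -> express -> apa -> motif.

``run_all`` consumes a :class:`RunConfig` (optionally loaded from YAML),
executes the stages in order, writes every stage table under the output
directory, and returns a machine-readable run report whose counts are
consistent with the written tables.  All thresholds default to the values
used throughout the library; the clustering RPM cutoff can be selected via
the ``preset`` field (``methods5`` or ``results0.5``).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd

from apaseq import __version__
from apaseq.annotate import annotate_sites, build_annotation_index
from apaseq.apa import (
    group_utrs,
    normalized_utr_length,
    summarize_switches,
    run_switch_tests,
    weighted_utr_length,
)
from apaseq.cluster import RPM_PRESETS, cluster_and_call
from apaseq.expression import call_degs, gene_boundaries, gene_expression
from apaseq.io_formats import read_gene_models, read_mapped_reads, write_sites_bed, write_table
from apaseq.motif import extract_flanks, iterative_hexamer_discovery, pas_presence
from apaseq.preprocess import run_filters
from apaseq.sequence import load_genome

log = logging.getLogger("apaseq")


@dataclass
class RunConfig:
    genome: str = ""
    genes: str = ""
    genes_format: str = "GTF"
    reads: dict[str, str] = field(default_factory=dict)  # sample -> path
    reads_format: str = "BED6"
    polya_db: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    preset: str = "methods5"
    linkage_nt: int = 40
    max_span: int = 40
    peak_halfwidth: int = 20
    min_total_rpm: float | None = None  # None -> preset value
    priming_window: int = 20
    priming_max_a: int = 12
    priming_side: str = "upstream"
    max_extension: int = 3000
    fdr_cut: float = 0.01
    fc_cut: float = 2.0
    switch_alpha: float = 0.01
    min_delta_usage: float = 0.05
    tol_known: int = 30
    tol_db: int = 30
    motif_top_n: int = 10
    motif_alpha: float = 0.01
    seed: int = 0

    @property
    def rpm_cutoff(self) -> float:
        if self.min_total_rpm is not None:
            return self.min_total_rpm
        return RPM_PRESETS[self.preset]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(str(c).split(":")) if isinstance(c, str) else tuple(c)
                                  for c in raw["comparisons"]]
        return cls(**raw)


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write stage tables plus ``report.json`` under ``out_dir``."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.genome, config.genes, *config.reads.values()):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")

    genome = load_genome(config.genome)
    genes = read_gene_models(config.genes, config.genes_format)
    samples = list(config.reads)
    report: dict = {"version": __version__, "config": _config_echo(config), "stages": {}}

    # --- filter -----------------------------------------------------------
    used_by_sample: dict[str, list] = {}
    filter_counts = {}
    for sample, path in config.reads.items():
        reads = list(read_mapped_reads(path, config.reads_format))
        used, rep = run_filters(
            reads, genome, config.priming_window, config.priming_max_a, config.priming_side
        )
        used_by_sample[sample] = used
        filter_counts[sample] = rep.as_dict()
        log.info("filter[%s]: %d -> %d used reads", sample, rep.n_input, len(used))
    library_sizes = {s: len(r) for s, r in used_by_sample.items()}
    report["stages"]["filter"] = filter_counts

    # --- cluster ----------------------------------------------------------
    pooled = [r for reads in used_by_sample.values() for r in reads]
    sites = cluster_and_call(
        pooled, library_sizes, config.linkage_nt, config.max_span,
        config.peak_halfwidth, config.rpm_cutoff,
    )
    write_sites_bed(sites, out / "sites.bed")
    report["stages"]["cluster"] = {"n_sites": len(sites), "min_total_rpm": config.rpm_cutoff}
    log.info("cluster: %d sites called", len(sites))

    # --- annotate ---------------------------------------------------------
    db = _load_db(config.polya_db) if config.polya_db else ()
    index = build_annotation_index(genes, db_sites=db)
    annotate_sites(sites, index, config.tol_known, config.tol_db)
    site_rows = []
    for s in sites:
        row = {
            "site_id": s.site_id, "chrom": s.chrom, "position": s.position,
            "strand": s.strand, "category": s.annotation_category,
            "host_gene": s.host_gene or "", "novelty": s.novelty_class,
            "total_rpm": s.total_rpm,
        }
        for name in samples:
            row[f"count_{name}"] = s.counts.get(name, 0)
            row[f"rpm_{name}"] = s.rpm.get(name, 0.0)
        site_rows.append(row)
    write_table(pd.DataFrame(site_rows), out / "sites_annotated.tsv")
    cat_counts = pd.Series([s.annotation_category for s in sites]).value_counts().to_dict()
    report["stages"]["annotate"] = {"categories": cat_counts}
    kept_sites = [s for s in sites if s.annotation_category != "mitochondrial"]

    # --- expression -------------------------------------------------------
    boundaries = gene_boundaries(genes, config.max_extension)
    expr = gene_expression(kept_sites, boundaries, samples)
    degs = call_degs(expr, config.comparisons, library_sizes,
                     config.fdr_cut, config.fc_cut)
    degs_out = degs.reset_index()
    write_table(degs_out, out / "expression.tsv")
    deg_counts = {
        f"{a}_vs_{b}": int(degs[f"deg_{a}_vs_{b}"].sum()) for a, b in config.comparisons
    }
    report["stages"]["expression"] = {"n_genes": len(expr), "n_degs": deg_counts}

    # --- apa --------------------------------------------------------------
    groups, discards = group_utrs(genes, kept_sites, config.max_extension)
    switch_rows, switch_summary = [], {}
    for a, b in config.comparisons:
        results = run_switch_tests(groups, a, b, config.switch_alpha, config.min_delta_usage)
        switch_summary[f"{a}_vs_{b}"] = summarize_switches(results)
        for r in results:
            switch_rows.append({"comparison": f"{a}_vs_{b}", **asdict(r)})
    write_table(pd.DataFrame(switch_rows), out / "apa_switches.tsv")
    length_rows = []
    for grp in groups:
        row = {"group_id": grp.group_id, "mode": grp.mode, "n_isoforms": len(grp.members)}
        for s in samples:
            w = weighted_utr_length(grp, s)
            n = normalized_utr_length(grp, s)
            row[f"weighted_{s}"] = w if w is not None else float("nan")
            row[f"normalized_{s}"] = n if n is not None else float("nan")
        length_rows.append(row)
    write_table(pd.DataFrame(length_rows), out / "utr_lengths.tsv")
    report["stages"]["apa"] = {
        "n_groups": len(groups), "n_discarded": len(discards), "switches": switch_summary,
    }

    # --- motif ------------------------------------------------------------
    flanks = extract_flanks(kept_sites, genome)
    hexamers = iterative_hexamer_discovery(flanks, top_n=config.motif_top_n,
                                           alpha=config.motif_alpha)
    write_table(pd.DataFrame([asdict(h) for h in hexamers]), out / "hexamers.tsv")
    pas_frac = pas_presence(flanks, [h.hexamer for h in hexamers]) if hexamers else float("nan")
    report["stages"]["motif"] = {
        "n_hexamers": len(hexamers),
        "pas_fraction_10_40_upstream": pas_frac,
    }

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _config_echo(config: RunConfig) -> dict:
    d = asdict(config)
    d["comparisons"] = [list(c) for c in config.comparisons]
    return d


def _load_db(path: str) -> list[tuple[str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+"))
    return out
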