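#!/usr/bin/env python
"""Annotate called sites by genomic category and novelty class.

Writes results/04_annotation_breakdown.tsv with the category x novelty
contingency (the pie-chart numbers of a site-annotation figure).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, called_sites

import pandas as pd

from apaseq.annotate import annotate_sites, build_annotation_index


def main():
    cfg, genome, genes, truth, sites, libs = called_sites()
    index = build_annotation_index(genes)
    annotate_sites(sites, index)
    df = pd.DataFrame({
        "category": [s.annotation_category for s in sites],
        "novelty": [s.novelty_class for s in sites],
    })
    table = df.value_counts().rename("n_sites").reset_index()
    out = RESULTS / "04_annotation_breakdown.tsv"
    table.to_csv(out, sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"annotation breakdown -> {out}")


if __name__ == "__main__":
    main()
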