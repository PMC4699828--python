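# apaseq

Poly(A)-site calling and alternative-polyadenylation (APA) analysis for
3'-end sequencing libraries (SAPAS/PAS-seq-style protocols), with a
synthetic-data generator that plants every structure the analysis relies on.

3'-end protocols prime on the poly(A) tail, so each read marks one cleavage
event. Comparing conditions — here the motivating design is germline stem
cells (GSC) against embryonic stem cells (ESC) and fibroblasts (MEF) — asks
four questions this package answers end to end:

1. **Where are the poly(A) sites?** Reads are filtered (unique alignment,
   ≤ 1 mismatch, quality), purged of internal-priming artifacts (> 12 A in
   the 20-nt window next to the cleavage site), pooled across samples, and
   clustered: positions within 40 nt single-link into clusters; clusters
   wider than 40 nt are split greedily at their highest-RPM positions. The
   cluster member with the highest summed RPM becomes the site, with
   RPM = count / (used reads in sample) × 10⁶.
2. **Where do they fall in the genome?** Annotation precedence
   3'UTR → exon → intron → 5'UTR → downstream (10 kb) → non-coding gene →
   mitochondrial → antisense → intergenic, plus known / database-supported /
   novel classification against annotated 3'UTR ends (± 30 bp).
3. **Which genes change expression?** Gene expression is the summed cluster
   RPM inside extended gene boundaries (≤ 3,000 nt downstream, no overlap);
   differential calls use two-sided Fisher's exact tests on read counts vs
   library totals, Benjamini-Hochberg FDR < 0.01, and fold change > 2.
4. **Which 3'UTRs switch sites?** Isoforms sharing a stop codon form a UTR
   group; the two most abundant isoforms give a proximal/distal pair tested
   by Fisher's exact test with Bonferroni correction (corrected p < 0.01 and
   |Δ proximal usage| > 5 points). Weighted 3'UTR length
   Σ(dᵢ·RPMᵢ)/Σ RPMᵢ and its normalized form (divided by the longest
   isoform) summarise global shortening/lengthening. PAS hexamers are
   discovered by iterative select-and-remove binomial enrichment against a
   composition-matched background.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(50 genes, three conditions with a genome-wide proximal-usage gradient
0.7 / 0.5 / 0.3, five planted switch genes, five planted 4-fold expression
changes, one A-rich internal-priming trap per gene):

```
python analysis/01_simulate.py
python analysis/02_filter_reads.py
python analysis/03_call_sites.py
...
python analysis/07_motifs.py
```

Selected output (tables land in `results/`):

```
GSC: 14189 reads in -> 13435 used; 0 trap reads survived the A-content filter
90 sites called from 36972 used reads
recall within 10 nt: 90/90; worst called-to-truth distance: 1 nt
GSC_vs_ESC: 5 DEGs called (5/5 planted recovered)
GSC vs MEF: shortened 27, lengthened 2 of 29 tested
condition  mean_weighted_nt  mean_normalized
      GSC        433.759741         0.482087
      ESC        515.406972         0.600595
      MEF        581.367034         0.708924
 rank hexamer    rna  observed  expected  p_bonferroni
    1  AATAAA AAUAAA        67  5.266322  4.202703e-59
    2  ATTAAA AUUAAA        10  1.308954  8.389052e-04
```

Reading this: every planted site is recalled to within 1 nt; all planted
expression and switch effects are recovered; the usage gradient produces the
strict mean-normalized-3'UTR-length ordering GSC < ESC < MEF (the shortening
pattern the design encodes); and the canonical PAS AAUAAA (with its main
variant AUUAAA) dominates the discovered hexamers.

The same pipeline is scriptable in one shot:

```
apaseq simulate --seed 7 --out study/
apaseq run --config run.yaml --out out/     # filter→cluster→annotate→express→apa→motif
```

or per stage (`apaseq filter|cluster|annotate|express|apa|motif`).

## Layout

- `src/apaseq/` — the library: `synthio` (generator), `io_formats`,
  `preprocess`, `cluster`, `annotate`, `expression`, `apa`, `motif`,
  `pipeline`, `evaluation`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and validation suites (`tests/oracles.py` holds
  the independent brute-force references).
- `docs/methods.md` — model, assumptions, parameter defaults, limitations.
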