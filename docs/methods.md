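# Methods

## Scope and data model

`apaseq` implements the downstream analysis of 3'-end sequencing libraries
in which each read's transcript-3' terminus marks one cleavage/
polyadenylation event. The pipeline consumes already-mapped reads (BED6 or
SAM; alignment is upstream of this package), a genome FASTA, and gene models
(GTF or BED12). All internal coordinates are 0-based half-open; GTF is
converted at the boundary. `cds_end` is stored as the half-open boundary
between the stop codon and the 3'UTR in transcript orientation (plus strand:
one past the last stop-codon base; minus strand: the smallest stop-codon
coordinate), which makes the 3'UTR interval and distance-from-stop
arithmetic uniform across strands.

## Read filters

Stage 1 retains quality-passing, uniquely aligned reads with at most one
mismatch. Stage 2 removes internal-priming artifacts: a read is discarded
when more than 12 of the 20 transcript-sense bases in the window adjacent to
its cleavage site are adenosines. The window side is configurable:

- `upstream` (default): the 20 transcribed bases ending at and including the
  cleavage base — the literal reading of "closest to the 5' end of the
  poly(A) junction";
- `downstream`: the 20 genomic bases just past the junction, the orientation
  most internal-priming filters in the field use.

Both are exposed because the phrase is genuinely ambiguous and real A-tracts
often span the junction; the threshold (> 12 of 20) is identical either
way. Windows truncated at contig ends are evaluated on the available bases
against the same absolute threshold (no proportional rule is defined
anywhere, and a truncated window can only be more conservative).

## Site calling

Used reads from all samples are pooled per (chromosome, strand). Positions
chain into raw clusters by single linkage with gap ≤ 40 nt (inclusive — the
boundary is tested). Expression is RPM: reads at a position per million used
reads in that sample. A raw cluster wider than 40 nt is split greedily: the
position with the highest summed RPM seeds a subcluster of all unassigned
positions within ± 20 nt, repeating until every read is assigned; the ± 20
half-width is chosen so every subcluster obeys the 40-nt ceiling, since no
split geometry is prescribed by the protocol description. The cluster
representative (the poly(A) site) is the member with the highest summed RPM;
ties break toward the transcript-5' side for determinism. Clusters with
total RPM (summed over samples) below a cutoff are dropped. Two cutoffs
circulate for this protocol — 5 RPM per cluster and total RPM > 0.5 across
libraries — so both ship as presets (`methods5`, default, and
`results0.5`); nothing downstream depends on which is chosen beyond site
count.

## Annotation

Categories are assigned in fixed precedence: 3'UTR, exon (CDS), intron,
5'UTR, downstream (the 10 kb past the gene's 3' terminus), non-coding gene,
mitochondrial, antisense, intergenic. All gene-linked categories match on
the read's own strand — 3'-end protocols are strand-specific — and only
antisense consults the opposite strand. Mitochondrial sites are flagged and
excluded from every downstream stage. When several genes match within one
category, the gene with the nearest annotated 3'UTR end wins (ties by
gene id). Novelty: `known` within 30 bp of an annotated 3'UTR end;
otherwise `db_supported` within 30 bp of a reference poly(A)-site database
entry (the database tolerance mirrors the known-site rule, as none is
specified for it); otherwise `novel`.

## Expression and differential calls

Gene boundaries are annotated spans extended downstream by at most 3,000 nt
without creating overlap; two extensions competing for one gap split it at
the midpoint (odd nucleotide to the left-hand gene — an arbitrary but
deterministic convention). Gene expression is the summed RPM of contained
same-strand sites. Differential expression per pairwise comparison: a
two-sided Fisher's exact test on `[[count_a, lib_a − count_a], [count_b,
lib_b − count_b]]` with library sizes = per-sample used-read totals,
Benjamini-Hochberg FDR within the comparison, fold change computed on RPM
with a 0.1-RPM pseudocount (stabilises zeros; the choice only matters for
genes near zero, which the FDR cut removes anyway). A gene is differentially
expressed iff FDR < 0.01 and max(FC, 1/FC) > 2 (strict). Genes whose total
count across samples is ≤ 10 are not tested by default (`min_total_count`,
optional). Fisher p-values come from `scipy.stats.fisher_exact`; the test
suite checks them against an exhaustive hypergeometric enumeration written
independently (agreement < 1e−9 on random tables). A Pearson-on-log2(RPM+1)
sample-correlation helper is provided for QC; its value is entirely
data-dependent and is not a validated quantity.

## 3'UTR groups, switch test, length metrics

3'UTR isoforms sharing a stop codon form one group; the group region runs
from the stop boundary to at most 3,000 nt past the last annotated 3'UTR
end, capped at the neighbouring gene. A group whose unextended 3'UTR
overlaps another gene, or whose extended region overlaps another group's,
is discarded (cross-gene overlap only; isoform overlap within one gene is
the normal tandem-UTR situation and is kept). lncRNA genes form a single
gene-wide group with distances measured from the gene 5' end.

The switch test takes the two most abundant isoforms (total read count
across samples; ties prefer the proximal member), labels the
closer-to-stop one proximal, and computes a two-sided Fisher p on
`[[prox_a, dist_a], [prox_b, dist_b]]`, Bonferroni-corrected by the number
of groups actually tested in that comparison (the natural family, since no
family size is prescribed). Significance requires corrected p < 0.01 and
|Δ proximal usage| > 0.05 — interpreted as percentage points of the
proximal fraction, the only scale-free reading — with a 1e−9 float guard so
an exactly-5-point change is not significant. `distal_to_proximal` (3'UTR
shortening in sample a) means proximal usage is higher in a.

Weighted 3'UTR length uses **all** member isoforms, Σ(dᵢ·RPMᵢ)/ΣRPMᵢ;
normalized length divides by the longest member distance, bounding it in
(0, 1] and damping long-UTR leverage. An all-sites chi-square over the full
site-by-sample table exists as an explicitly optional exploration
(`apa.all_sites_chi2`, off by default) — no formula for an all-sites switch
statistic is defined by the protocol this package follows.

## PAS hexamer discovery

Flanks (± 100 nt, transcript strand, cleavage base at relative position 0)
are scanned for 6-mers. The background expectation per hexamer uses the
pooled mononucleotide composition of the current flank set: per-window
probability p = Π(base frequencies), per-flank containment probability
1 − (1 − p)^W for W windows, expected count = the sum over flanks.
Containment is counted per flank (presence/absence), matching the removal
rule. Each iteration emits the hexamer with the smallest one-sided binomial
exceedance p-value, Bonferroni-corrected over all 4⁶ = 4,096 hexamers
(the significance rule is unnamed in the protocol; binomial exceedance with
Bonferroni is the conservative standard choice), removes every flank
containing it, re-estimates the background, and stops at ten motifs or when
nothing passes α = 0.01. Motifs are DNA internally and also rendered as RNA
(AAUAAA). PAS presence is the fraction of sites with any motif match
starting 10–40 nt upstream of the cleavage site. The ± 500-nt span around
each site can be exported as five contiguous 200-nt subregion FASTAs for
external motif tools (e.g. MEME); the motif elicitation itself is out of
scope.

## Synthetic data generator

`synthio` emulates exactly the structures the analysis assumes, nothing
more:

- **Genes**: uniform non-overlapping placement, same-strand neighbours
  ≥ 6,000 nt apart so the 3,000-nt boundary extension is unambiguous;
  single-exon models with 100-nt 5'UTR and 200–400-nt CDS; 1–3 poly(A)
  sites per 3'UTR (default mix 0.4/0.4/0.2, matching roughly half of genes
  carrying tandem sites at ~2 sites per multi-site gene); proximal site
  150–400 nt from the stop, subsequent sites 400–800 nt further; ~6%
  lncRNA.
- **PAS**: with probability `pas_rate` (default 0.85, consistent with
  "over 80%" of real sites carrying AAUAAA-family signals) a hexamer
  (AATAAA 80% / ATTAAA 20%) is written with match start 10–40 nt upstream
  of the site.
- **Traps**: per gene, one 20-nt window with ≥ 13 A (15 planted) ending at
  a mid-CDS position; a configurable fraction of reads originates exactly
  there. Every true site's upstream window is capped at ≤ 12 A (planted PAS
  bases protected), so at zero noise the internal-priming filter removes
  100% of trap reads and 0% of true-site reads *by construction* — the
  tests assert this guarantee, which is what makes the filter's perfect
  score on synthetic data an invariant rather than an empirical finding.
- **Usage**: per-condition proximal-usage fractions, default 0.7 (GSC) /
  0.5 (ESC) / 0.3 (MEF) — the qualitative gradient that germline stem
  cells use proximal sites most. The remaining mass splits evenly over the
  distal sites. Planted switch genes use 0.8 vs 0.2 between the first
  condition and the rest (alternating direction); planted DE genes get a
  4-fold multiplier (alternating up/down) in the first condition.
- **Reads**: per gene and condition, Poisson(depth × fold) reads,
  multinomial over sites by usage, cleavage positions jittered by a
  discretised normal (default sd = 2 nt — no quantitative cleavage-
  heterogeneity model is published for this protocol; 2 nt exercises
  clustering without ever splitting a true site) and clamped to the
  chromosome. Reads carry uniqueness/mismatch/quality flags so the filters
  have something to do.

What the generator does **not** emulate: sequence composition of real
3'UTRs (background is uniform ACGT), overlapping or multi-isoform exon
structure, expression dynamic range (genes share one depth unless a fold is
planted), biased strand coverage, mismapping, and chimeric or linker
artifacts. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated generative model, not performance on real
libraries — in particular, real internal-priming filters misfire on genuine
A-rich 3'UTRs, a failure mode the capped-window construction deliberately
excludes from the specificity invariant.

## Numerical and design choices

- Linkage boundary: gap of exactly 40 nt chains (inclusive reading).
- All tie-breaks (peak choice, representative site, top-two isoforms) are
  deterministic and documented at the function level; end-to-end reruns are
  byte-identical.
- Fisher two-sided p-values follow the standard "sum of tables no more
  probable than observed" definition with the usual 1e−7 relative tie
  tolerance.
- The switch Δ-usage cut uses a 1e−9 absolute guard against float noise at
  the 0.05 boundary.
- Degenerate inputs: empty read streams produce zero-filled reports; groups
  with < 2 isoforms or an all-zero sample are skipped with a reason;
  zero-expression samples yield missing (None/NaN) length metrics; a
  genome too small for the requested gene count fails fast with the
  required minimum length.

## Validation experiment sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments at the same sizes: 1,000 random clustering instances (≤ 50
positions) against a union-find + independent-greedy oracle; 500 random 2×2
tables against hypergeometric enumeration; trap specificity on a 50-gene
zero-noise genome; site recall on a 50-gene genome at depth 250 with sd 2
jitter; switch power/FPR over 100 seeds × (100 switch + 100 null groups) at
200 reads/sample/group; the length ordering on a 60-gene three-condition
study; hexamer recovery over 100 seeds × 2,000 flanks (60% AATAAA, 20%
ATTAAA) plus matched null runs; DEG power/FPR over 100 seeds × (10 planted
+ 90 null genes) at depth 500. These sizes keep the whole validation run at
a couple of minutes on one CPU while leaving binomial standard errors well
below the asserted margins.

## Known limitations

- The pipeline calls sites from pooled samples only; merging site sets from
  independent runs is unsupported.
- Unstranded data is rejected rather than strand-inferred.
- The Fisher DE test treats reads as independent draws from the library;
  like all count-based two-sample exact tests it is anti-conservative under
  biological overdispersion, which is why count-model alternatives (e.g.
  negative-binomial GLMs) are the right tool for replicated designs. It is
  the defined method here; no replicate structure exists in the target
  design.
- GO/pathway enrichment, external motif elicitation, and comparisons
  against external site databases beyond simple positional overlap are out
  of scope.
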