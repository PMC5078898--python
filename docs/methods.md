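# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED) internally and on disk; a tag
is the 5′ start of a uniquely mapped read, reduced to a point (an
optional fragment extension exists in the config but defaults to 0 bp —
no fragment-length model is assumed). Strand is stored but ignored by
window and gene counting, matching unstranded library preparation.
Duplicate tag coordinates are kept by default; a config flag collapses
them.

## Enrichment segmentation

Window counts use a tiling that advances full windows by the step while
they fit and closes each chromosome with one clipped tail window, so with
step = window the windows partition the chromosome and counts sum to the
library size. The default window is 1000 bp with step window/2
("sliding"); `optimize_window_size` audits a candidate grid
{250, 500, 1000, 2000, 4000} and returns the size maximizing the number
of called domains (ties to the smaller size).

The permutation null redraws every tag position uniformly within its
chromosome, preserving per-chromosome totals — the tag-level Monte-Carlo
scheme — and pools all permuted window counts. This is a homogeneous
null: no mappability mask or CpG-density covariate is modeled, which is
exactly the assumption under which the synthetic generator operates.
The count threshold is the smallest integer t with tail probability
P(null > t) ≤ α; requesting α below 1/(permutations × windows) raises an
error rather than returning a vacuous threshold. Empirical p-values use
the add-one rule (r+1)/(n+1) so no window gets p = 0. Significant
windows merge when overlapping or book-ended; a merged domain records its
best window count, that window's empirical p, and the summed counts of
its constituent windows (overlapping windows double-count by
construction; the per-region tag counts used for differential testing are
recounted from the tag sets instead).

Two stringencies matter. Window-level α = 0.01 is the calibration
setting: on background-only data the called fraction must track α. For
actual domain calling the pipeline's benchmark analyses use α = 1e-5 — a
genome-wide-corrected threshold, since at α = 0.01 a 10 Mb genome yields
~200 false windows by construction — and a 500 bp window, because
resolving 1-kb domains with ≥ 50 % boundary accuracy requires a window no
longer than the domain (a 1000 bp window at step 500 can smear a 1 kb
domain over ~2.5 kb of merged calls).

## Differential methylation

Enrichment territory is merged across all samples of an assay and
re-tiled into 5-kb units (the whole-region mode is a flag). The default
test is the 2×2 chi-square (no continuity correction) of
[count, library − count] across conditions on pooled counts — chosen
because the motivating design has two pools per condition, too few for
stable per-replicate dispersion — with the replicate-aware NB Wald test
as the alternative; that test falls back to chi-square with a logged
warning below two replicates per condition. The "difference > 50 tags"
filter is applied to the library-size-normalized difference
count_B·(lib_A/lib_B) − count_A (raw mode is a flag). q-values are BH per
assay over all tested units; Storey's estimator is reserved for the
expression stage. Both counts zero gives p = 1 by convention.

## Expression

Counting assigns a tag to a gene when its position falls in an exon
(whole-span mode available); tags hitting multiple genes are dropped and
counted in the report, preserving the identity
assigned + ambiguous + unassigned = library size.

The differential test is a deliberately compact NB analysis, a documented
stand-in for full NB-GLM packages with numerical differences expected:

- size factors: median of ratios to the per-gene geometric mean, over
  genes positive in all samples, normalized to geometric mean 1;
- dispersion: per-gene method-of-moments from within-condition variances
  of normalized counts, Var(K/s) ≈ μ·mean(1/s) + αμ², then averaged in
  ~20 mean-rank bins (bin **means**, not medians — the raw estimates are
  right-skewed and a median biases the trend low, which we observed to
  make the null anti-conservative), floored at 1e-8;
- Wald test on the condition log-ratio with delta-method standard error
  Var(log q̂_c) = (1/n_c²)(Σ_j 1/(q̂_c s_j) + n_c α) and a half-tag
  pseudo-mean per condition so zero groups stay finite. The reference is
  the standard normal: the dispersion enters through a trend shared
  across many genes, so no per-gene degrees-of-freedom penalty applies —
  validated by label-permutation simulation (KS vs U(0,1), p > 0.01 at
  2000 genes). No log2FC shrinkage is applied.
- multiplicity: Storey q-values; π₀ from the smoother (cubic spline
  through π₀(λ) on λ = 0.05…0.95, read at λ = 0.95, clipped to (0, 1]).
  Below 100 p-values π₀ is fixed at 1 with a warning. With π₀ = 1 the
  q-values equal BH exactly. All-zero genes get NaN p/q and do not enter
  the correction.

## Integration

DMRs are ranked by (q, p, |normalized diff|, coordinates) — the
coordinate key only for full determinism — annotated to the nearest TSS
within 50 kb measured from the DMR midpoint (edge-anchor and 25 kb modes
are config options), truncated to the top 2000, then reduced to one
best-ranked DMR per gene. Equidistant TSS ties break to the
lexicographically smaller gene id. The signed distance is negative
upstream of the gene, strand-aware.

Top-N overlap tests are one-sided hypergeometric (P(overlap ≥ observed))
of the top-1000 DMR gene set against the top-1000 smallest-p expression
genes, reported for all four direction pairs; the universe is the full
annotated gene set of the study.

Meta-gene matrices: fixed-bp flanks (default 2 kb in 20 bins) and the
gene body rescaled to 50 bins regardless of length; values are tags per
bin divided by bin width; minus-strand rows are flipped so 5′ is left;
the matrix is divided by its median positive value (all-zero matrices
stay zero rather than NaN); the stored ceiling is the 0.80 quantile of
the normalized values and is applied at render time only. Flank bins
running off a chromosome end use the clipped width. Genes shorter than
the body bin count are rejected. The intragenic score is the summed
gene-body density difference (condition B − A) of the two
median-normalized matrices; it is antisymmetric in (A, B), and the
descending sort is stable. The decile contrast orders genes by the signed
expression Wald statistic and compares intragenic scores of the top vs
bottom decile with a one-sided Welch t-test.

## Enrichment engine

Category content is always an input file (TSV category→gene); no
ontology is bundled, and database-dependent category findings are
explicitly not benchmark targets. Fisher is one-sided (enrichment);
categories empty after intersection with the universe are skipped and
logged. The length-bias-aware test treats the per-gene weights (e.g.
exonic length) as selection propensities and uses Wallenius' noncentral
hypergeometric distribution with category odds = mean weight inside the
category / mean weight outside; with equal weights it reduces exactly to
Fisher. The KS variant compares a ranked statistic inside vs outside each
category (two-sample, tie-safe). BH across categories; the significance
convention is q < 0.01.

## Synthetic data

The generator emulates: homogeneous Poisson tag background (default 0.01
tags/bp ≈ 100k tags per 10 Mb library); planted enrichment domains
(default 200 × 1 kb at fold 8, placed ≥ 2 kb apart) realized as extra
Poisson tags at rate (fold−1)·background inside the domain (sub-unity
effective folds are realized by thinning); DMRs as fold-ratio changes
(default ratio 3, half up / half down) on existing domains in the
irradiated condition — not de-novo domains, so merged-territory testing
is exercised; non-overlapping gene models (lognormal lengths, 1–4 exons
anchored at both span ends); NB RNA counts (default mean 100, dispersion
0.1, Var = μ + αμ², per-replicate lognormal depth factors, σ = 0.2) with
a DE subset at |log2FC| = 1; and a coupled subset of up-regulated genes
that also receive an intragenic 5hmC domain covering the central half of
the gene body, gaining by the DMR fold ratio in the irradiated condition.
One `numpy` Generator seeded once drives every stage.

What it does **not** emulate — hence what passing benchmarks do not show
about real data: mappability and GC/CpG-density structure in the
background, fragment-length smearing, input/IgG contrast, antibody
efficiency differences between 5mC and 5hmC, batch effects between pools,
isoform structure, and ontology term correlation. Recovery rates here are
upper bounds for data with those artifacts.

## Benchmark problem sizes

Null calibration: 20 background-only 10 Mb libraries of 100k tags, 500
permutations, α = 0.01. Domain recovery: 200 domains, window 500,
α = 1e-5, scored at ≥ 50 % reciprocal overlap. DMR recovery: 1000
domains / 100 DMRs, two pools per condition, 150 permutations per
library. Expression: 2000 genes, 4 vs 4. End-to-end coupling: 5000 genes
on 25 Mb, 100 coupled genes, 120 permutations per library, plus ten
single-pool replicates for the decile contrast and an uncoupled control.
Weighted enrichment: 2000-gene universe, 100 bias replicates.

## Known limitations

- The expression benchmark's power clause at Storey q < 0.05 sits near
  0.4–0.5 under these conditions for any calibrated NB test (the oracle
  Wald z is ≈ 3.0 and adaptive FDR thresholds land near z ≈ 3); power at
  raw p < 0.05 is ≈ 0.8. The suite asserts the q-based target and
  reports both numbers rather than loosening the check.
- The chi-square path assumes pooled counts are the unit of evidence;
  overdispersion between pools of the same condition inflates its
  significance. The NB path is the guard, at the cost of power with two
  pools.
- The permutation null conditions only on per-chromosome tag totals;
  with strong non-uniform mappability a matched null (or an input
  library) would be required.
- Wallenius correction assumes selection propensity proportional to the
  supplied weight; it does not estimate the propensity function from the
  data.
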