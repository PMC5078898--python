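# dipseq

A reusable pipeline for DIP-Seq/RNA-Seq analysis of DNA-methylation
change, built around the workflow used to study radiation-induced 5mC and
5hmC remodeling in the hippocampus: methyl- and hydroxymethyl-DNA
immunoprecipitation tags are segmented into enriched domains against a
Monte-Carlo permutation background, domains are tested for differential
(hydroxy)methylation between conditions, RNA tag counts are tested for
differential expression, and the two layers are integrated — nearest-TSS
annotation, top-N overlap statistics, expression-sorted meta-gene density
heatmaps, intragenic-difference ranking and gene-set enrichment.

It is aimed at analysts who have mapped tag coordinates (BED), gene
models (BED12/refFlat) and RNA counts (TSV) and want the whole chain, or
any single stage, as tested, seed-reproducible library calls. The package
ships a synthetic-data generator that plants enriched domains, DMRs, DE
genes and a methylation–expression coupling with full truth tables, so
every stage can be validated by recovery scoring rather than by eye.

## The statistics at the core

**Segmentation.** Tags are counted in sliding windows (default 1000 bp,
step w/2). The null is built by redrawing every tag position uniformly
within its chromosome (preserving per-chromosome totals) for N
permutations; pooled permuted window counts give a count threshold with
tail probability ≤ α and add-one empirical p-values
p = (r+1)/(n+1). Windows above threshold merge (overlap/book-end) into
enriched domains. A window optimizer picks the size maximizing the number
of called domains over a candidate grid.

**Differential methylation.** Per-sample domains are unioned across
samples and re-tiled into 5-kb testing units. Each unit is tested by a
2×2 chi-square of region count vs remaining library across conditions
(default; pooled counts), or a replicate-aware negative-binomial Wald
test. DMRs require BH q < 0.01 **and** library-normalized tag difference
|count_B·(lib_A/lib_B) − count_A| > 50.

**Expression.** A compact DESeq-style NB analysis: median-of-ratios size
factors, mean-trended method-of-moments dispersions (Var = μ + αμ²),
Wald test on the condition log-ratio, Storey q-values with the smoother
π₀ estimate (q_i = min_{j≥i} π₀·m·p_(j)/j).

**Integration.** DMRs ranked by (q, p, |diff|) are annotated to the
nearest TSS within 50 kb (25 kb alternate), one record per gene, top 2000
kept. Top-1000 DMR genes × top-1000 DE genes are tested per direction
pair by one-sided Fisher exact. Meta-gene matrices hold median-normalized
tag density (fixed-bp flanks, body rescaled to a common bin count, color
ceiling at the 80 % quantile); genes are ranked by the summed gene-body
density difference between conditions (top 500). Enrichment over
user-supplied category maps is one-sided Fisher, Wallenius noncentral
hypergeometric for length-bias correction, or a two-sample KS on a ranked
statistic.

## Worked example

The numbered drivers under `analysis/` run one synthetic study (10 Mb
genome, 2000 genes, two assays, sham vs irradiated, two pools each; 200
planted domains per assay, 100 DMRs at fold ratio 3, 300 DE genes, 100
genes coupled to an intragenic 5hmC gain):

```bash
python analysis/01_simulate.py
python analysis/02_segment.py
python analysis/03_differential_methylation.py
python analysis/04_differential_expression.py
python analysis/05_integration.py
python analysis/06_enrichment.py
```

Output of the differential and integration steps on this dataset:

```
5mC: called 101 DMRs; sensitivity 1.00 vs 100 planted, empirical FDR 0.010
5hmC: called 209 DMRs; sensitivity 1.00 vs 200 planted, empirical FDR 0.043
175 genes at q < 0.05; 168/300 planted DE genes recovered, 7 false positives (FDP 0.040)
meth_direction expr_direction  n_meth  n_expr  overlap            p
            up             up     150     968      126 5.404727e-21
            up           down     150    1000       23 1.000000e+00
          down             up      59     968       19 9.964308e-01
          down           down      59    1000       40 3.849652e-03
100/100 coupled genes in the top-500 intragenic-difference ranking
top-vs-bottom expression decile intragenic score difference 115.88 (one-sided p = 1.03e-22)
```

Read: both DMR sets are recovered with the FDR controlled at the nominal
level; the only strong directional overlap is genes with jointly
*increased* 5hmC and *increased* expression (p ≈ 10⁻²¹), exactly the
planted coupling; those genes also sit at the top of the
intragenic-difference ranking, and the gene-body 5hmC gain concentrates
in the top expression decile. The enrichment stage then flags the planted
`coupled_truth` category (Fisher p ≈ 10⁻¹¹⁰) while 20 random categories
stay null.

The same stages are available as a CLI
(`dipseq simulate|segment|diff-meth|diff-expr|integrate|enrich|run-all`);
`run-all` writes a manifest (config snapshot, input digests, seed,
per-stage row counts) and reruns with the same seed are byte-identical.

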