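"""Benchmark analyses: the pipeline run against planted synthetic truth.

Each function generates its own data at the stated study conditions, runs
the relevant pipeline stages from scratch, and returns the measured
quantities (calibration fractions, recovery rates, oracle discrepancies).
They are shared by the test suite and by ``scripts/acceptance.py``.

Problem sizes follow the standard conditions: 10 Mb single-chromosome
genomes with ~0.01 tags/bp libraries for the segmentation benchmarks,
2000–5000 genes for the expression and integration benchmarks. Domain
recovery and the end-to-end run segment at a 500 bp window with a
genome-wide-corrected threshold (alpha 1e-5): resolving 1-kb domains with
>= 50 % boundary accuracy requires a window no longer than the domain,
and window-level alpha 0.01 is reserved for the null-calibration check
where it is the quantity under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from . import differential as diff
from . import integration as integ
from . import segmentation as seg
from .expression import bh_qvalues, estimate_pi0, storey_qvalues, test_expression
from .genome import GenomicInterval
from .pipeline import merge_tagsets
from .scoring import score_dmr_recovery, score_domain_recovery
from .simulate import (CONDITION_A, CONDITION_B, SimParams, plant_truth,
                       simulate_dataset, simulate_genome_and_genes,
                       simulate_rna_counts)


def _background_params(**kw) -> SimParams:
    base = dict(n_genes=0, n_de_genes=0, n_coupled_genes=0,
                n_domains=0, n_dmrs=0, n_pools=1)
    base.update(kw)
    return SimParams(**base)


# ------------------------------------------------------ null calibration


def segmentation_null_calibration(
    seed: int,
    n_datasets: int = 20,
    n_permutations: int = 500,
    alpha: float = 0.01,
    window_bp: int = 1000,
    library_size: int = 100_000,
) -> dict[str, float]:
    """Fraction of windows called on background-only data.

    Background-only libraries (uniform Poisson tags, no planted domains)
    are segmented at the stated alpha; a calibrated permutation null keeps
    the mean called fraction near alpha.
    """
    params = _background_params(library_size=library_size)
    fractions = []
    for i in range(n_datasets):
        ds = simulate_dataset(params, seed=seed + i)
        tags = ds.dip_tags[("5hmC", CONDITION_A, 1)]
        wc = seg.count_windows(tags, ds.genome, window_bp)
        null = seg.permutation_null(tags, ds.genome, window_bp,
                                    n_permutations=n_permutations,
                                    seed=seed + 1000 + i)
        threshold = null.threshold(alpha)
        counts = wc.all_counts()
        fractions.append(float((counts > threshold).mean()))
    return {"mean_fraction_called": float(np.mean(fractions)),
            "alpha": alpha, "n_datasets": n_datasets}


# ------------------------------------------------------ domain recovery


def domain_recovery(
    seed: int,
    n_domains: int = 200,
    n_permutations: int = 500,
    window_bp: int = 500,
    alpha: float = 1e-5,
) -> dict[str, float]:
    """Sensitivity/precision for planted 1-kb enrichment domains at fold 8,
    scored at >= 50 % reciprocal overlap."""
    params = _background_params(n_domains=n_domains)
    ds = simulate_dataset(params, seed=seed)
    tags = ds.dip_tags[("5hmC", CONDITION_A, 1)]
    domains, _ = seg.segment(tags, ds.genome, window_bp=window_bp,
                             n_permutations=n_permutations, alpha=alpha,
                             seed=seed + 1)
    score = score_domain_recovery([d.interval for d in domains],
                                  ds.truth.domain_intervals("5hmC"))
    return {"sensitivity": score["sensitivity"], "precision": score["precision"],
            "n_called": score["n_called"], "n_truth": score["n_truth"]}


# ------------------------------------------------------ DMR recovery


def dmr_recovery(
    seed: int,
    n_domains: int = 1000,
    n_dmrs: int = 100,
    n_permutations: int = 150,
    window_bp: int = 500,
    alpha: float = 1e-5,
    q_threshold: float = 0.01,
    min_tag_diff: float = 50.0,
) -> dict[str, float]:
    """Differential recovery: planted fold-ratio-3 DMRs among enriched
    regions, two pools per condition, chi-square path, q < 0.01 and
    normalized difference > 50 in 5-kb units."""
    params = SimParams(n_genes=0, n_de_genes=0, n_coupled_genes=0,
                       n_domains=n_domains, n_dmrs=n_dmrs, n_pools=2)
    ds = simulate_dataset(params, seed=seed)
    domain_lists = []
    for tags in ds.dip_tags.values():
        domains, _ = seg.segment(tags, ds.genome, window_bp=window_bp,
                                 n_permutations=n_permutations, alpha=alpha,
                                 seed=seed + 2)
        domain_lists.append(domains)
    regions = diff.merge_regions(domain_lists, 5000)
    tags_a = [ds.dip_tags[("5hmC", CONDITION_A, i)] for i in (1, 2)]
    tags_b = [ds.dip_tags[("5hmC", CONDITION_B, i)] for i in (1, 2)]
    tested = diff.test_regions(regions, tags_a, tags_b, assay="5hmC")
    dmrs = diff.call_dmrs(tested, q_threshold, min_tag_diff)
    truth = ds.truth.dmr_intervals("5hmC")
    dirs = [d.direction for d in ds.truth.planted_dmrs if d.assay == "5hmC"]
    score = score_dmr_recovery(dmrs, truth, dirs)
    return {"sensitivity": score["sensitivity"], "empirical_fdr": score["fdr"],
            "n_regions_tested": len(tested), "n_dmrs_called": len(dmrs)}


# ------------------------------------------------------ exact-test oracles


def fisher_chisq_oracle_check(max_margin: int = 30) -> dict[str, float]:
    """Compare the 2x2 tests with independent closed forms.

    The one-sided Fisher p for every distinct table with all margins
    <= ``max_margin`` is recomputed by exact hypergeometric enumeration
    with integer binomials; the chi-square statistic is recomputed from
    its textbook closed form N(ad-bc)^2 / (row and column products).
    Returns the maximum absolute discrepancies.
    """
    configs = set()
    r = range(max_margin + 1)
    for a, b, c, d in itertools.product(r, r, r, r):
        if a + b <= max_margin and c + d <= max_margin \
                and a + c <= max_margin and b + d <= max_margin \
                and a + b + c + d > 0:
            configs.add((a + b + c + d, a + b, a + c, a))
    max_fisher_err = 0.0
    for N, K, n, k in configs:
        # P(X >= k) for X ~ Hypergeom(N, K, n), exact integer arithmetic
        denom = math.comb(N, n)
        num = sum(math.comb(K, x) * math.comb(N - K, n - x)
                  for x in range(k, min(K, n) + 1))
        exact = num / denom
        ours = float(stats.hypergeom.sf(k - 1, N, K, n))
        max_fisher_err = max(max_fisher_err, abs(ours - exact))
    max_chisq_err = 0.0
    for a, b, c, d in [(30, 970, 5, 995), (10, 90, 20, 80), (1, 9, 9, 1),
                       (50, 50, 25, 75), (3, 0, 0, 3)]:
        la, lb = a + b, c + d
        stat, _ = diff.test_region_chisq(a, c, la, lb)
        N = a + b + c + d
        row1, row2 = a + b, c + d
        col1, col2 = a + c, b + d
        closed = N * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
        max_chisq_err = max(max_chisq_err, abs(stat - closed))
    return {"max_fisher_abs_err": max_fisher_err,
            "max_chisq_abs_err": max_chisq_err,
            "n_tables": len(configs)}


# ------------------------------------------------------ Storey q-values


def storey_behaviour(seed: int, m: int = 5000, n_vectors: int = 10) -> dict[str, float]:
    """Storey-vs-BH reduction at pi0 = 1 and the pi0 estimate on uniform p."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(200, 2000)))
        max_diff = max(max_diff, float(np.max(np.abs(
            storey_qvalues(p, pi0=1.0) - bh_qvalues(p)))))
    pi0 = estimate_pi0(rng.uniform(size=m))
    return {"max_storey_bh_diff": max_diff, "pi0_uniform": float(pi0)}


# ------------------------------------------------------ expression calibration and power


def _rna_table(params: SimParams, seed: int):
    rng = np.random.default_rng(seed)
    genome, genes = simulate_genome_and_genes(params, rng)
    truth = plant_truth(genome, genes, params, rng)
    ca = simulate_rna_counts(genes, truth, params, CONDITION_A, rng=rng)
    cb = simulate_rna_counts(genes, truth, params, CONDITION_B, rng=rng)
    counts = pd.concat([ca, cb], axis=1)
    condition_of = {c: CONDITION_A if c.startswith(CONDITION_A) else CONDITION_B
                    for c in counts.columns}
    return counts, condition_of, truth


def expression_calibration_and_power(
    seed: int, n_genes: int = 2000, n_de: int = 200
) -> dict[str, float]:
    """Null uniformity (label permutation) and power on planted log2fc = 1.

    The null table has no differential genes, so the condition labels are
    an arbitrary permutation of exchangeable replicates; p-values should
    be uniform. Power is the fraction of planted genes (log2fc 1, base
    mean 100, dispersion 0.1, 4 vs 4) at Storey q < 0.05; the fraction at
    raw p < 0.05 is reported alongside.
    """
    base = dict(n_genes=n_genes, n_domains=0, n_dmrs=0, n_coupled_genes=0,
                chrom_length_bp=20_000_000)
    null_counts, cond, _ = _rna_table(SimParams(n_de_genes=0, **base), seed)
    res0 = test_expression(null_counts, cond, condition_b=CONDITION_B)
    ks = stats.kstest(res0["p"].dropna().to_numpy(), "uniform")
    counts, cond, truth = _rna_table(SimParams(n_de_genes=n_de, **base), seed + 1)
    res = test_expression(counts, cond, condition_b=CONDITION_B)
    de_ids = [g for g, _ in truth.de_genes]
    power_q = float(np.mean(res.loc[de_ids, "storey_q"] < 0.05))
    power_p = float(np.mean(res.loc[de_ids, "p"] < 0.05))
    return {"null_ks_p": float(ks.pvalue), "power_q05": power_q,
            "power_raw_p05": power_p}


# ------------------------------------------------------ end-to-end coupling recovery


def _coupling_params(coupled: bool) -> SimParams:
    return SimParams(
        n_genes=5000, n_de_genes=300,
        n_coupled_genes=100 if coupled else 0,
        n_domains=100, n_dmrs=50, chrom_length_bp=25_000_000, n_pools=2,
    )


def _intragenic_ranking(ds, tags_a, tags_b, expr):
    ordered = expr.sort_values("stat", ascending=False, kind="stable")
    gene_by_id = {g.gene_id: g for g in ds.genes}
    ordered_genes = [gene_by_id[g] for g in ordered.index if g in gene_by_id]
    ma = integ.metagene_matrix(merge_tagsets(tags_a, "pooled_a"), ordered_genes)
    mb = integ.metagene_matrix(merge_tagsets(tags_b, "pooled_b"), ordered_genes)
    return integ.rank_intragenic_difference(ma, mb, top_n=500)


def coupling_recovery(
    seed: int,
    coupled: bool = True,
    n_permutations: int = 120,
) -> dict[str, float]:
    """Full-pipeline recovery of the joint 5hmC/expression structure.

    Runs segmentation, differential methylation, TSS annotation,
    expression testing, the directional top-1000 x top-1000 overlap and
    the intragenic-difference ranking on one simulated dataset with (or,
    as control, without) 100 coupled genes among 5000.
    """
    params = _coupling_params(coupled)
    ds = simulate_dataset(params, seed=seed)
    domain_lists = []
    for tags in ds.dip_tags.values():
        domains, _ = seg.segment(tags, ds.genome, window_bp=500,
                                 n_permutations=n_permutations, alpha=1e-5,
                                 seed=seed + 3)
        domain_lists.append(domains)
    regions = diff.merge_regions(domain_lists, 5000)
    tags_a = [ds.dip_tags[("5hmC", CONDITION_A, i)] for i in (1, 2)]
    tags_b = [ds.dip_tags[("5hmC", CONDITION_B, i)] for i in (1, 2)]
    tested = diff.test_regions(regions, tags_a, tags_b, assay="5hmC")
    dmrs = diff.call_dmrs(tested, 0.01, 50.0)
    annotated = integ.annotate_dmrs(dmrs, ds.genes, max_dist_bp=50_000, top_n=2000)
    expr = test_expression(ds.rna_counts, ds.condition_of,
                           condition_b=CONDITION_B)
    universe = set(g.gene_id for g in ds.genes)
    overlap = integ.topn_overlap_by_direction(annotated, expr, universe,
                                              top_n=1000)
    up_up = overlap[(overlap["meth_direction"] == "up")
                    & (overlap["expr_direction"] == "up")].iloc[0]
    ranking = _intragenic_ranking(ds, tags_a, tags_b, expr)
    out = {"overlap_up_up_p": float(up_up["p"]),
           "overlap_up_up_n": int(up_up["overlap"]),
           "n_dmrs": len(dmrs)}
    if coupled:
        coupled_set = set(ds.truth.coupled_genes)
        in_top = ranking[ranking["in_top_n"]]["gene_id"].isin(coupled_set).sum()
        out["coupled_in_top500_fraction"] = in_top / len(coupled_set)
    _, decile_p = integ.decile_score_test(ranking, expr)
    out["decile_p"] = float(decile_p)
    return out


def coupling_decile_replicates(
    seed: int, coupled: bool = True, n_replicates: int = 10
) -> dict[str, float]:
    """Top- vs bottom-expression-decile intragenic score over replicates.

    Each replicate is a fresh simulation (single pool per condition; no
    segmentation needed for this readout); reports how many replicates
    reach p < 0.01 on the one-sided decile test.
    """
    params = _coupling_params(coupled)
    params.n_pools = 1
    n_sig = 0
    for i in range(n_replicates):
        ds = simulate_dataset(params, seed=seed + 10 * (i + 1))
        tags_a = [ds.dip_tags[("5hmC", CONDITION_A, 1)]]
        tags_b = [ds.dip_tags[("5hmC", CONDITION_B, 1)]]
        expr = test_expression(ds.rna_counts, ds.condition_of,
                               condition_b=CONDITION_B)
        ranking = _intragenic_ranking(ds, tags_a, tags_b, expr)
        _, p = integ.decile_score_test(ranking, expr)
        if p < 0.01:
            n_sig += 1
    return {"n_significant": n_sig, "n_replicates": n_replicates}


# ------------------------------------------------------ weighted-enrichment reduction


def weighted_enrichment_behaviour(
    seed: int, n_replicates: int = 100
) -> dict[str, float]:
    """Wallenius reduction to Fisher and absorption of planted length bias.

    Reduction: on random sets with unit weights the Wallenius p must
    match the Fisher p. Bias: the universe is half long genes (weight 4)
    and half short (weight 1); the gene list is sampled with probability
    proportional to weight and the category is made of long genes, so the
    unweighted test sees spurious enrichment which the weighted test
    discounts (weighted p >= unweighted p).
    """
    from .enrichment import enrich_fisher, enrich_weighted

    rng = np.random.default_rng(seed)
    universe = {f"g{i:04d}" for i in range(2000)}
    genes = sorted(universe)
    max_reduction_diff = 0.0
    for _ in range(10):
        cat = {"c": set(rng.choice(genes, size=150, replace=False))}
        gene_set = set(rng.choice(genes, size=300, replace=False))
        unit = {g: 1.0 for g in genes}
        pf = enrich_fisher(gene_set, cat, universe)["p"].iloc[0]
        pw = enrich_weighted(gene_set, cat, universe, unit)["p"].iloc[0]
        max_reduction_diff = max(max_reduction_diff, abs(pf - pw))
    long_genes = genes[:1000]
    weights = {g: (4.0 if g in set(long_genes) else 1.0) for g in genes}
    probs = np.array([weights[g] for g in genes], dtype=float)
    probs /= probs.sum()
    n_absorbed = 0
    for _ in range(n_replicates):
        gene_set = set(rng.choice(genes, size=300, replace=False, p=probs))
        cat = {"long": set(rng.choice(long_genes, size=150, replace=False))}
        pf = enrich_fisher(gene_set, cat, universe)["p"].iloc[0]
        pw = enrich_weighted(gene_set, cat, universe, weights)["p"].iloc[0]
        if pw >= pf:
            n_absorbed += 1
    return {"max_reduction_diff": float(max_reduction_diff),
            "bias_absorbed_fraction": n_absorbed / n_replicates}
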