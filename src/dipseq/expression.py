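"""RNA tag counting and differential expression.

Counting assigns a tag to a gene when its position falls inside an exon
of that gene (whole-span mode available); tags hitting more than one gene
are discarded and logged. Differential testing is a compact
DESeq-style negative-binomial analysis: median-of-ratios size factors,
mean-trended method-of-moments dispersions, a Wald test on the condition
log-ratio, and Storey q-values (pi0 estimated by the smoother method) for
multiplicity. It is a self-contained stand-in for heavier NB-GLM
packages, so modest numerical differences from those are expected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, TagSet
from .nbstats import (mom_dispersion, nb_wald, size_factors_median_of_ratios,
                      trended_dispersion)

logger = logging.getLogger(__name__)


@dataclass
class CountingReport:
    counts: pd.Series  # per-gene tag counts
    n_ambiguous: int  # tags overlapping more than one gene, dropped
    n_unassigned: int  # intergenic / intronic tags

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.n_ambiguous + self.n_unassigned


def count_gene_tags(
    rna_tags: TagSet, genes: list[GeneModel], mode: str = "exon"
) -> CountingReport:
    """Count RNA tags per gene; ambiguous tags are dropped and logged.

    ``mode='exon'`` counts a tag only when its position lies within an
    exon; ``'span'`` accepts anywhere in the gene span. Strand is ignored
    (unstranded libraries).
    """
    if mode not in ("exon", "span"):
        raise ValueError("mode must be 'exon' or 'span'")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        if mode == "span":
            tree.addi(g.start, g.end, g.gene_id)
        else:
            for e in (g.exons or (g.span,)):
                tree.addi(e.start, e.end, g.gene_id)
    counts = {g.gene_id: 0 for g in genes}
    n_ambiguous = 0
    n_unassigned = 0
    for chrom in rna_tags.chroms:
        tree = trees.get(chrom)
        positions = rna_tags.positions_on(chrom)
        if tree is None:
            n_unassigned += positions.size
            continue
        for pos in positions:
            hits = {iv.data for iv in tree.at(int(pos))}
            if len(hits) == 1:
                counts[next(iter(hits))] += 1
            elif len(hits) > 1:
                n_ambiguous += 1
            else:
                n_unassigned += 1
    if n_ambiguous:
        logger.info("dropped %d ambiguous tags (multiple genes)", n_ambiguous)
    series = pd.Series(counts, name=rna_tags.sample_id)
    series.index.name = "gene_id"
    return CountingReport(series, n_ambiguous, n_unassigned)


def test_expression(
    counts: pd.DataFrame,
    condition_of: dict[str, str],
    condition_b: str | None = None,
) -> pd.DataFrame:
    """Differential expression across two conditions.

    ``counts`` is genes x samples; ``condition_of`` labels each column.
    Returns a per-gene table with base_mean, log2fc (B vs A, unshrunk),
    Wald p and Storey q. Genes with zero counts everywhere get NaN p/q and
    are excluded from the multiplicity correction.
    """
    labels = [condition_of[c] for c in counts.columns]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 conditions, got {uniq}")
    cond_b = condition_b or uniq[1]
    group_b = np.array([lab == cond_b for lab in labels])
    if group_b.sum() < 2 or (~group_b).sum() < 2:
        raise ValueError("need >= 2 replicates per condition")
    mat = counts.to_numpy(dtype=float)
    sf = size_factors_median_of_ratios(mat)
    alpha_raw, mu = mom_dispersion(mat, sf, group_b)
    alpha = trended_dispersion(mu, alpha_raw)
    res = nb_wald(mat, sf, group_b, alpha)
    out = pd.DataFrame(
        {
            "base_mean": res["base_mean"],
            "log2fc": res["log2fc"],
            "stat": res["stat"],
            "p": res["p"],
            "dispersion": alpha,
        },
        index=counts.index,
    )
    out["storey_q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "storey_q"] = storey_qvalues(out.loc[tested, "p"].to_numpy())
    return out


# ------------------------------------------------------------- q-values


def estimate_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on a
    lambda grid (default 0.05..0.95 step 0.05), smoothed with a cubic
    spline, and read off at the largest lambda; the result is clipped to
    (0, 1]. Fewer than 100 p-values force pi0 = 1 with a warning, since
    the smoother is unstable there.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 100:
        warnings.warn("fewer than 100 p-values: fixing pi0 = 1")
        return 1.0
    lambdas = np.arange(0.05, 0.951, 0.05) if lambdas is None else lambdas
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_l, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; with pi0 = 1 they coincide with BH exactly."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
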