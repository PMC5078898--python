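"""Generic gene-set enrichment for DMR- and expression-derived lists.

Three tests over user-supplied category maps (database content is an
input, never bundled): a one-sided Fisher/hypergeometric test, a
Wallenius noncentral hypergeometric test that absorbs selection bias
(e.g. longer genes being likelier to enter an RNA-derived list), and a
two-sample KS test comparing a ranked statistic inside vs outside each
category. Categories are BH-adjusted; the conventional significance call
is q < 0.01.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CategoryMap = dict[str, set]


def read_category_map(path: str | Path) -> CategoryMap:
    """Read a two-column TSV (category_id, gene_id) into a CategoryMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "gene"],
                     dtype=str, comment="#")
    out: CategoryMap = {}
    for cat, sub in df.groupby("category"):
        out[str(cat)] = set(sub["gene"])
    return out


def enrich_fisher(
    gene_set: set,
    categories: CategoryMap,
    universe: set,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric) enrichment per category.

    p = P(overlap >= observed) drawing |gene_set| genes from the universe.
    Categories empty after intersection with the universe are skipped and
    logged. BH q-values run across the tested categories; ``significant``
    marks q < ``q_threshold``.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    n_u, n_set = len(universe), len(gene_set)
    rows = []
    for cat, members in categories.items():
        m = members & universe
        if not m:
            logger.info("category %s empty after intersecting universe; skipped", cat)
            continue
        k = len(gene_set & m)
        p = float(stats.hypergeom.sf(k - 1, n_u, len(m), n_set))
        a, b = k, len(m) - k
        c, d = n_set - k, n_u - len(m) - (n_set - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((cat, len(m), k, float(odds), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["category", "n_category", "n_overlap",
                                     "odds_ratio", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def enrich_weighted(
    gene_set: set,
    categories: CategoryMap,
    universe: set,
    weights: dict[str, float],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Selection-bias-aware enrichment via Wallenius noncentral
    hypergeometric sampling.

    ``weights`` are per-gene selection propensities (for RNA-derived
    lists, the gene's mappable length under length-proportional
    sampling). The Wallenius odds for a category are the mean weight of
    category genes over the mean weight of non-category genes, so a
    category of heavy genes has its apparent enrichment discounted. With
    all weights equal the test reduces exactly to :func:`enrich_fisher`.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    missing = universe - set(weights)
    if missing:
        raise ValueError(f"{len(missing)} universe genes lack weights")
    if any(weights[g] <= 0 for g in universe):
        raise ValueError("weights must be positive")
    n_u, n_set = len(universe), len(gene_set)
    rows = []
    for cat, members in categories.items():
        m = members & universe
        if not m:
            logger.info("category %s empty after intersecting universe; skipped", cat)
            continue
        k = len(gene_set & m)
        w_in = np.mean([weights[g] for g in m])
        out_genes = universe - m
        w_out = np.mean([weights[g] for g in out_genes]) if out_genes else w_in
        omega = w_in / w_out
        if n_set == 0:
            p = 1.0
        else:
            dist = stats.nchypergeom_wallenius(n_u, len(m), n_set, omega)
            p = float(dist.sf(k - 1))
        rows.append((cat, len(m), k, float(omega), min(max(p, 0.0), 1.0)))
    df = pd.DataFrame(rows, columns=["category", "n_category", "n_overlap",
                                     "odds", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


def enrich_ks(
    statistic: pd.Series,
    categories: CategoryMap,
    min_category_size: int = 3,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Two-sample KS test: statistic inside vs outside each category.

    ``statistic`` is indexed by gene_id and must cover the whole
    universe. Categories with fewer than ``min_category_size`` members in
    the universe are skipped. Ties are handled by the empirical-CDF
    convention of the two-sample KS statistic, so the result does not
    depend on tie order.
    """
    universe = set(statistic.index)
    rows = []
    for cat, members in categories.items():
        m = members & universe
        if len(m) < min_category_size:
            logger.info("category %s below minimum size; skipped", cat)
            continue
        inside = statistic.loc[sorted(m)].to_numpy()
        outside = statistic.loc[sorted(universe - m)].to_numpy()
        res = stats.ks_2samp(inside, outside)
        rows.append((cat, len(m), float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["category", "n_category", "D", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < q_threshold
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df
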