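"""Negative-binomial Wald testing shared by the methylation and
expression stages.

The model is the standard count-GLM formulation: counts K_ij ~ NB(mu_ij,
alpha_i) with mu_ij = s_j * q_ic, where s_j is a per-sample size factor,
q_ic the condition mean of gene/region i, and alpha_i the dispersion
(Var = mu + alpha * mu^2). Dispersions are method-of-moments estimates
pooled along a mean-ordered trend; the test is a Wald z on the condition
log-ratio with a half-count pseudo mean to keep zero groups finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

DISPERSION_FLOOR = 1e-8


def size_factors_median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a genes x samples count matrix.

    Each sample's factor is the median across genes of its count divided
    by the gene's geometric mean; only genes with all-positive counts
    enter. Factors are scaled to geometric mean 1. A table whose columns
    are exact scalar multiples of one reference returns those scalars
    (up to the overall normalization).
    """
    counts = np.asarray(counts, dtype=float)
    pos = np.all(counts > 0, axis=1)
    if not pos.any():
        raise ValueError("no gene has positive counts in every sample")
    sub = counts[pos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def mom_dispersion(
    counts: np.ndarray, sf: np.ndarray, group_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene raw method-of-moments dispersion and overall mean.

    Uses within-condition variances of normalized counts, so planted
    condition differences do not inflate the estimate:
    Var(K/s) ~= mu * mean(1/s) + alpha * mu^2.
    """
    y = counts / sf
    a, b = y[:, ~group_b], y[:, group_b]
    na, nb = a.shape[1], b.shape[1]
    var_a = a.var(axis=1, ddof=1) if na > 1 else np.zeros(len(y))
    var_b = b.var(axis=1, ddof=1) if nb > 1 else np.zeros(len(y))
    dof_a, dof_b = max(na - 1, 0), max(nb - 1, 0)
    pooled_var = (dof_a * var_a + dof_b * var_b) / max(dof_a + dof_b, 1)
    mu = 0.5 * (a.mean(axis=1) + b.mean(axis=1))
    m1 = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu * m1) / np.square(mu)
    alpha[~np.isfinite(alpha)] = 0.0
    return alpha, mu


def trended_dispersion(
    mu: np.ndarray, alpha_raw: np.ndarray, n_bins: int = 20,
    floor: float = DISPERSION_FLOOR,
) -> np.ndarray:
    """Smooth raw dispersions along the mean: binned means on mean rank.

    Per-gene moment estimates are individually very noisy at typical
    replicate numbers but approximately unbiased, so genes share the mean
    raw dispersion of their mean-rank bin (a median would bias the trend
    low because the estimates are right-skewed). Floored at ``floor``.
    """
    m = len(mu)
    if m == 0:
        return np.empty(0)
    n_bins = max(1, min(n_bins, m // 50)) if m >= 100 else 1
    order = np.argsort(mu, kind="stable")
    edges = np.linspace(0, m, n_bins + 1).astype(int)
    alpha = np.empty(m)
    for i in range(n_bins):
        idx = order[edges[i]:edges[i + 1]]
        alpha[idx] = np.mean(alpha_raw[idx])
    return np.maximum(alpha, floor)


def nb_wald(
    counts: np.ndarray,
    sf: np.ndarray,
    group_b: np.ndarray,
    alpha: np.ndarray | float,
) -> dict[str, np.ndarray]:
    """Vectorized Wald test of condition B vs A on NB counts.

    Returns base_mean, log2fc, stat and p for each row of ``counts``.
    Rows that are all zero get NaN p. The condition means receive a
    half-tag pseudo count (in normalized units, spread over the
    condition's samples) so single-zero groups stay finite; the standard
    error follows the delta method on the log condition mean. Because the
    dispersion enters through a mean-rank trend shared across many genes
    rather than a noisy per-gene estimate, the standard normal is the
    appropriate reference for the Wald statistic even at small replicate
    numbers (a per-gene-estimated scale would call for a t reference).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    sf = np.asarray(sf, dtype=float)
    group_b = np.asarray(group_b, dtype=bool)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (counts.shape[0],))
    y = counts / sf
    a, b = y[:, ~group_b], y[:, group_b]
    sf_a, sf_b = sf[~group_b], sf[group_b]
    na, nb = a.shape[1], b.shape[1]
    qa = a.mean(axis=1)
    qb = b.mean(axis=1)
    pseudo_a = 0.5 / (na * sf_a.mean())
    pseudo_b = 0.5 / (nb * sf_b.mean())
    qa_s, qb_s = qa + pseudo_a, qb + pseudo_b
    # Var(log q_c) ~= (1/n_c^2) * sum_j (1/(q_c s_j) + alpha)  (delta method)
    se2_a = (1.0 / na**2) * (np.sum(1.0 / sf_a) / qa_s + na * alpha)
    se2_b = (1.0 / nb**2) * (np.sum(1.0 / sf_b) / qb_s + nb * alpha)
    log_ratio = np.log(qb_s) - np.log(qa_s)
    z = log_ratio / np.sqrt(se2_a + se2_b)
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = counts.sum(axis=1) == 0
    p[all_zero] = np.nan
    z = np.where(all_zero, 0.0, z)
    return {
        "base_mean": y.mean(axis=1),
        "log2fc": log_ratio / np.log(2.0),
        "stat": z,
        "p": p,
        "mean_a": qa,
        "mean_b": qb,
    }
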