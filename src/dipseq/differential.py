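"""Differential methylation: merge enrichment territory, test, filter.

Per-sample enriched domains are unioned across samples, the union is
re-tiled into fixed testing units (default 5 kb), and each unit is tested
for a condition difference either by a 2x2 chi-square on pooled counts
against the remaining library (the default, matching a two-pools-per-
condition design) or by a replicate-aware negative-binomial Wald test.
Units pass the DMR filter when the BH-adjusted q-value is below the
threshold AND the library-size-normalized tag difference exceeds the
minimum (defaults q < 0.01, |difference| > 50 tags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomicInterval, TagSet, merge_intervals
from .nbstats import nb_wald
from .segmentation import EnrichedDomain

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmrRecord:
    """One significant differentially (hydroxy)methylated region."""

    interval: GenomicInterval
    assay: str
    count_a: float
    count_b: float
    norm_diff: float
    stat: float
    p: float
    q: float
    direction: str  # "up"/"down" in condition B vs A


def merge_regions(
    domain_lists: list[list[EnrichedDomain]] | list[list[GenomicInterval]],
    resolution_bp: int | None = 5000,
) -> list[GenomicInterval]:
    """Union per-sample enriched domains and re-tile into testing units.

    ``resolution_bp=None`` returns whole merged regions; otherwise each
    merged region is cut into resolution-sized tiles, the last clipped to
    the region end.
    """
    intervals: list[GenomicInterval] = []
    for lst in domain_lists:
        for d in lst:
            intervals.append(d.interval if isinstance(d, EnrichedDomain) else d)
    if not intervals:
        return []
    merged = merge_intervals(intervals)
    if resolution_bp is None:
        return merged
    tiles: list[GenomicInterval] = []
    for iv in merged:
        for start in range(iv.start, iv.end, resolution_bp):
            tiles.append(GenomicInterval(iv.chrom, start,
                                         min(start + resolution_bp, iv.end)))
    return tiles


def normalized_difference(
    count_a: float, count_b: float, lib_a: float, lib_b: float
) -> float:
    """Condition-B count rescaled to the A library, minus the A count."""
    return count_b * (lib_a / lib_b) - count_a


def test_region_chisq(
    count_a: int, count_b: int, lib_a: int, lib_b: int, correction: bool = False
) -> tuple[float, float]:
    """2x2 chi-square of region vs remaining library across conditions.

    Table rows are conditions, columns (in-region, rest-of-library).
    Returns (statistic, p); both counts zero gives (0, 1) by convention.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if count_a == 0 and count_b == 0:
        return 0.0, 1.0
    table = np.array([[count_a, lib_a - count_a], [count_b, lib_b - count_b]],
                     dtype=float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def test_region_nb(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    libs_a: np.ndarray,
    libs_b: np.ndarray,
    dispersion: float | None = None,
) -> tuple[float, float]:
    """Replicate-aware NB Wald test of one region.

    Library sizes act as size-factor offsets (scaled to geometric mean 1);
    the dispersion defaults to a pooled method-of-moments estimate from
    the replicate counts. Falls back to chi-square on pooled counts, with
    a logged warning, when either condition has fewer than 2 replicates.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    libs_a = np.asarray(libs_a, dtype=float)
    libs_b = np.asarray(libs_b, dtype=float)
    if counts_a.size < 2 or counts_b.size < 2:
        logger.warning("fewer than 2 replicates per condition: "
                       "falling back to pooled chi-square")
        return test_region_chisq(int(counts_a.sum()), int(counts_b.sum()),
                                 int(libs_a.sum()), int(libs_b.sum()))
    if counts_a.sum() == 0 and counts_b.sum() == 0:
        return 0.0, 1.0
    libs = np.concatenate([libs_a, libs_b])
    sf = libs / np.exp(np.mean(np.log(libs)))
    counts = np.concatenate([counts_a, counts_b])[None, :]
    group_b = np.concatenate(
        [np.zeros(counts_a.size, bool), np.ones(counts_b.size, bool)])
    if dispersion is None:
        y = counts[0] / sf
        ya, yb = y[~group_b], y[group_b]
        pooled_var = 0.5 * (ya.var(ddof=1) + yb.var(ddof=1))
        mu = 0.5 * (ya.mean() + yb.mean())
        dispersion = 0.0 if mu == 0 else (pooled_var - mu * np.mean(1 / sf)) / mu**2
        dispersion = max(dispersion, 1e-8)
    res = nb_wald(counts, sf, group_b, dispersion)
    return float(res["stat"][0]), float(res["p"][0])


def test_regions(
    regions: list[GenomicInterval],
    tagsets_a: list[TagSet],
    tagsets_b: list[TagSet],
    assay: str | None = None,
    test: str = "chisq",
    diff_mode: str = "normalized",
) -> pd.DataFrame:
    """Count tags per region in each sample and test every region.

    ``test='chisq'`` pools replicate libraries per condition; ``'nb'``
    keeps them separate. The returned table carries counts, the
    (normalized or raw) tag difference, statistic and p per region.
    """
    counts_a = np.stack([t.count_intervals(regions) for t in tagsets_a])
    counts_b = np.stack([t.count_intervals(regions) for t in tagsets_b])
    libs_a = np.array([t.library_size for t in tagsets_a], dtype=float)
    libs_b = np.array([t.library_size for t in tagsets_b], dtype=float)
    pooled_a, pooled_b = counts_a.sum(axis=0), counts_b.sum(axis=0)
    lib_a, lib_b = libs_a.sum(), libs_b.sum()
    rows = []
    for i, iv in enumerate(regions):
        if test == "nb" and len(tagsets_a) >= 2 and len(tagsets_b) >= 2:
            stat, p = test_region_nb(counts_a[:, i], counts_b[:, i], libs_a, libs_b)
        else:
            stat, p = test_region_chisq(int(pooled_a[i]), int(pooled_b[i]),
                                        int(lib_a), int(lib_b))
        if diff_mode == "normalized":
            diff = normalized_difference(pooled_a[i], pooled_b[i], lib_a, lib_b)
        else:
            diff = float(pooled_b[i] - pooled_a[i])
        rows.append((iv.chrom, iv.start, iv.end, int(pooled_a[i]), int(pooled_b[i]),
                     diff, stat, p))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count_a", "count_b",
                                     "norm_diff", "stat", "p"])
    df["assay"] = assay if assay is not None else "NA"
    return df


def call_dmrs(
    tested: pd.DataFrame,
    q_threshold: float = 0.01,
    min_tag_diff: float = 50.0,
) -> pd.DataFrame:
    """Apply BH and the joint significance/effect filter.

    q-values are computed per assay over all tested regions; a region is a
    DMR iff q < ``q_threshold`` and |normalized difference| >
    ``min_tag_diff``. Direction follows the sign of the difference
    (up = more tags in condition B).
    """
    if len(tested) == 0:
        out = tested.copy()
        out["q"] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=str)
        return out
    tested = tested.copy()
    tested["q"] = np.nan
    for assay, idx in tested.groupby("assay").groups.items():
        p = tested.loc[idx, "p"].to_numpy()
        tested.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    tested["direction"] = np.where(tested["norm_diff"] >= 0, "up", "down")
    keep = (tested["q"] < q_threshold) & (tested["norm_diff"].abs() > min_tag_diff)
    n_q = int((tested["q"] < q_threshold).sum())
    logger.info("DMR filter: %d/%d pass q<%g, %d also pass |diff|>%g",
                n_q, len(tested), q_threshold, int(keep.sum()), min_tag_diff)
    return tested[keep].reset_index(drop=True)


def dmr_venn(
    sets: dict[str, set],
    universe: set | int,
) -> pd.DataFrame:
    """Pairwise overlap counts with one-sided hypergeometric p-values.

    ``sets`` maps a label (e.g. '5hmC_up') to a set of gene identifiers;
    the universe is the annotatable gene universe (a set or its size).
    p is P(overlap >= observed) under random draws from the universe.
    """
    n_universe = len(universe) if not isinstance(universe, int) else universe
    if n_universe == 0:
        raise ValueError("empty universe")
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = sets[a], sets[b]
            k = len(sa & sb)
            p = float(stats.hypergeom.sf(k - 1, n_universe, len(sa), len(sb)))
            rows.append((a, b, len(sa), len(sb), k, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b",
                                       "overlap", "p"])


def count_interval_overlaps(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> int:
    """Number of intervals in ``a`` overlapping (>= 1 bp) any interval in ``b``."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    count = 0
    for iv in a:
        ivs = merged.get(iv.chrom, [])
        starts = np.array([m.start for m in ivs])
        ends = np.array([m.end for m in ivs])
        if ivs and bool(np.any((starts < iv.end) & (iv.start < ends))):
            count += 1
    return count


def dmrs_to_records(df: pd.DataFrame) -> list[DmrRecord]:
    return [
        DmrRecord(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.assay,
                  r.count_a, r.count_b, r.norm_diff, r.stat, r.p, r.q, r.direction)
        for r in df.itertuples(index=False)
    ]
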