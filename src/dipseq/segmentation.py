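"""Enriched-domain segmentation against a Monte-Carlo permutation null.

Tags are counted in sliding windows (default 1000 bp, step = half the
window). The background model is built by redrawing every tag position
uniformly within its chromosome — preserving per-chromosome tag totals —
for ``n_permutations`` rounds and pooling all permuted window counts into
one null distribution. Windows whose observed count exceeds the null
count threshold at the requested tail probability are merged (overlapping
or book-ended) into enriched domains; each domain carries the add-one
empirical p-value of its best window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, TagSet


@dataclass
class WindowCounts:
    """Per-window tag counts for one sample over the whole genome."""

    window_bp: int
    step_bp: int
    chroms: list[str]
    starts: dict[str, np.ndarray]  # window starts per chromosome
    ends: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    @property
    def n_windows(self) -> int:
        return int(sum(s.size for s in self.starts.values()))

    def all_counts(self) -> np.ndarray:
        parts = [self.counts[c] for c in self.chroms]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)


@dataclass(frozen=True)
class EnrichedDomain:
    """A merged run of significant windows."""

    interval: GenomicInterval
    max_count: int  # best single-window count
    p_value: float  # add-one empirical p of the best window
    merged_count: int  # summed counts of constituent significant windows


def window_grid(chrom_length: int, window_bp: int, step_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Window starts/ends tiling ``[0, chrom_length)``.

    Full windows advance by ``step_bp`` while they fit; if they do not
    reach the chromosome end a final clipped window covers the tail, so
    with step == window the windows partition the chromosome exactly.
    """
    if window_bp >= chrom_length:
        return np.array([0]), np.array([chrom_length])
    last_full = (chrom_length - window_bp) // step_bp
    starts = np.arange(0, last_full + 1) * step_bp
    ends = starts + window_bp
    if ends[-1] < chrom_length:
        starts = np.append(starts, starts[-1] + step_bp)
        ends = np.append(ends, chrom_length)
    return starts.astype(np.int64), ends.astype(np.int64)


def count_windows(
    tags: TagSet, genome: Genome, window_bp: int, step_bp: int | None = None
) -> WindowCounts:
    """Count tag positions in each half-open sliding window."""
    step_bp = step_bp or max(1, window_bp // 2)
    if not (1 <= step_bp <= window_bp):
        raise ValueError("require window_bp >= step_bp >= 1")
    starts, ends, counts = {}, {}, {}
    for chrom in genome.chrom_names:
        s, e = window_grid(genome.length_of(chrom), window_bp, step_bp)
        pos = tags.positions_on(chrom)
        counts[chrom] = (
            np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
        ).astype(np.int64)
        starts[chrom], ends[chrom] = s, e
    return WindowCounts(window_bp, step_bp, genome.chrom_names, starts, ends, counts)


@dataclass
class PermutationNull:
    """Pooled null distribution of window counts from uniform re-placement."""

    window_bp: int
    step_bp: int
    n_permutations: int
    histogram: np.ndarray  # histogram[k] = number of null windows with count k
    seed: int | None = None

    def __post_init__(self):
        self._tail = np.cumsum(self.histogram[::-1])[::-1]  # _tail[k] = #null >= k
        self.total = int(self.histogram.sum())

    def tail_prob(self, count: int) -> float:
        """P(null count > count)."""
        idx = count + 1
        if idx >= self._tail.size:
            return 0.0
        return float(self._tail[idx]) / self.total

    def threshold(self, alpha: float) -> int:
        """Smallest count ``t`` with P(null > t) <= alpha.

        Raises when the permutation resolution (1 / total null windows)
        cannot support the requested alpha.
        """
        resolution = 1.0 / self.total
        if alpha < resolution:
            raise ValueError(
                f"alpha={alpha:g} below the permutation resolution "
                f"{resolution:g} = 1/(n_permutations x n_windows); "
                "increase n_permutations"
            )
        # tail_prob is non-increasing in t; find the first t meeting alpha
        probs = self._tail[1:] / self.total  # probs[t] = P(null > t)
        t = int(np.searchsorted(-probs, -alpha, side="left"))
        return t

    def p_value(self, count: int) -> float:
        """Add-one empirical p: (#null >= count + 1) / (total + 1)."""
        idx = min(count, self._tail.size - 1)
        r = float(self._tail[idx]) if count < self._tail.size else 0.0
        return (r + 1.0) / (self.total + 1.0)


def permutation_null(
    tags: TagSet,
    genome: Genome,
    window_bp: int,
    step_bp: int | None = None,
    n_permutations: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationNull:
    """Build the pooled permutation null for one sample's window counts."""
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for a usable null")
    step_bp = step_bp or max(1, window_bp // 2)
    rng = rng if rng is not None else np.random.default_rng(seed)
    grids = {
        chrom: window_grid(genome.length_of(chrom), window_bp, step_bp)
        for chrom in genome.chrom_names
    }
    n_tags = {c: tags.positions_on(c).size for c in genome.chrom_names}
    hist = np.zeros(16, dtype=np.int64)
    for _ in range(n_permutations):
        for chrom in genome.chrom_names:
            n = n_tags[chrom]
            s, e = grids[chrom]
            if n == 0:
                counts = np.zeros(s.size, dtype=np.int64)
            else:
                pos = np.sort(rng.integers(0, genome.length_of(chrom), size=n))
                counts = np.searchsorted(pos, e) - np.searchsorted(pos, s)
            top = int(counts.max(initial=0))
            if top + 1 > hist.size:
                hist = np.concatenate([hist, np.zeros(top + 1 - hist.size, np.int64)])
            hist += np.bincount(counts, minlength=hist.size)
    return PermutationNull(window_bp, step_bp, n_permutations, hist, seed)


def call_domains(
    wc: WindowCounts,
    threshold: int,
    null: PermutationNull | None = None,
) -> list[EnrichedDomain]:
    """Merge windows with count > threshold into enriched domains.

    Overlapping or book-ended significant windows join a single domain;
    the domain p-value is the minimum add-one empirical p among its
    windows (1.0 when no null is supplied).
    """
    domains: list[EnrichedDomain] = []
    for chrom in wc.chroms:
        counts = wc.counts[chrom]
        sig = np.flatnonzero(counts > threshold)
        if sig.size == 0:
            continue
        starts, ends = wc.starts[chrom], wc.ends[chrom]
        run_start = 0
        runs = []
        for i in range(1, sig.size + 1):
            if i == sig.size or starts[sig[i]] > ends[sig[i - 1]]:
                runs.append(sig[run_start:i])
                run_start = i
        for run in runs:
            iv = GenomicInterval(chrom, int(starts[run[0]]), int(ends[run[-1]]))
            best = int(counts[run].max())
            p = null.p_value(best) if null is not None else 1.0
            domains.append(EnrichedDomain(iv, best, p, int(counts[run].sum())))
    return domains


def segment(
    tags: TagSet,
    genome: Genome,
    window_bp: int = 1000,
    step_bp: int | None = None,
    n_permutations: int = 500,
    alpha: float = 0.01,
    seed: int | None = None,
) -> tuple[list[EnrichedDomain], PermutationNull]:
    """Convenience wrapper: counts, permutation null, domain calls."""
    wc = count_windows(tags, genome, window_bp, step_bp)
    null = permutation_null(tags, genome, window_bp, step_bp,
                            n_permutations=n_permutations, seed=seed)
    domains = call_domains(wc, null.threshold(alpha), null)
    return domains, null


DEFAULT_CANDIDATE_WINDOWS = (250, 500, 1000, 2000, 4000)


def optimize_window_size(
    tags: TagSet,
    genome: Genome,
    candidate_sizes: tuple[int, ...] = DEFAULT_CANDIDATE_WINDOWS,
    n_permutations: int = 200,
    alpha: float = 0.01,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the window size that maximizes the number of enriched domains.

    Runs full segmentation per candidate (step = size / 2) and returns the
    winner plus the per-size audit table; ties break toward the smaller
    window.
    """
    if len(candidate_sizes) == 0:
        raise ValueError("need at least one candidate window size")
    rows = []
    for size in sorted(candidate_sizes):
        domains, null = segment(tags, genome, window_bp=size,
                                n_permutations=n_permutations, alpha=alpha, seed=seed)
        rows.append({
            "window_bp": size,
            "n_domains": len(domains),
            "threshold": null.threshold(alpha),
            "total_domain_bp": sum(d.interval.length for d in domains),
        })
    table = pd.DataFrame(rows)
    best = table.sort_values(["n_domains", "window_bp"],
                             ascending=[False, True], kind="stable").iloc[0]
    return int(best["window_bp"]), table


def domains_to_frame(domains: list[EnrichedDomain]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.interval.chrom, d.interval.start, d.interval.end,
             d.max_count, d.p_value, d.merged_count)
            for d in domains
        ],
        columns=["chrom", "start", "end", "max_count", "p_value", "merged_count"],
    )
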