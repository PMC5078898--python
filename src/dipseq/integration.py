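"""Connect DMRs to genes and to expression.

Four analyses: (1) nearest-TSS annotation of ranked DMRs within a
distance limit (50 kb default, 25 kb alternate), non-redundant per gene;
(2) Fisher overlap of top-N DMR-derived gene sets with top-N
differentially expressed genes, reported per direction pair; (3)
meta-gene tag-density matrices — fixed-bp flanks, gene bodies rescaled to
a common bin count, median-normalized, with a quantile color ceiling for
rendering; (4) ranking genes by the normalized intragenic density
difference between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, TagSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------- annotation


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    max_dist_bp: int = 50_000,
    top_n: int = 2000,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Assign ranked DMRs to their nearest TSS and keep one per gene.

    DMRs are ranked by q, then p, then |normalized difference| (then
    coordinates, for full determinism); each is annotated to the nearest
    TSS within ``max_dist_bp`` measured from the DMR midpoint (or nearer
    edge with ``anchor='edge'``), the list is truncated to ``top_n``, and
    only the best-ranked DMR per gene is kept. The signed distance is
    negative upstream of the gene (strand-aware). Equidistant TSS ties
    break toward the lexicographically smaller gene_id.
    """
    if anchor not in ("midpoint", "edge"):
        raise ValueError("anchor must be 'midpoint' or 'edge'")
    if len(dmrs) == 0:
        return dmrs.assign(gene_id=pd.Series(dtype=str),
                           tss_distance=pd.Series(dtype=int))
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom in {g.chrom for g in genes}:
        sub = sorted((g for g in genes if g.chrom == chrom),
                     key=lambda g: (g.tss, g.gene_id))
        tss_by_chrom[chrom] = (np.array([g.tss for g in sub]), sub)

    ranked = dmrs.copy()
    ranked["_absdiff"] = ranked["norm_diff"].abs()
    ranked = ranked.sort_values(
        ["q", "p", "_absdiff", "chrom", "start"],
        ascending=[True, True, False, True, True], kind="stable",
    ).drop(columns="_absdiff")

    rows = []
    for rec in ranked.itertuples(index=False):
        entry = tss_by_chrom.get(rec.chrom)
        if entry is None:
            continue
        tss_arr, sub = entry
        if anchor == "midpoint":
            anchors = [(rec.start + rec.end) // 2]
        else:
            anchors = [rec.start, rec.end - 1]
        best_gene, best_abs = None, None
        for a in anchors:
            idx = np.searchsorted(tss_arr, a)
            for j in range(max(0, idx - 2), min(len(sub), idx + 2)):
                d = abs(int(tss_arr[j]) - a)
                g = sub[j]
                if best_abs is None or d < best_abs or (
                    d == best_abs and g.gene_id < best_gene.gene_id
                ):
                    best_gene, best_abs, best_anchor = g, d, a
        if best_gene is None or best_abs > max_dist_bp:
            continue
        signed = best_anchor - best_gene.tss
        if best_gene.strand == "-":
            signed = -signed
        rows.append({**rec._asdict(), "gene_id": best_gene.gene_id,
                     "tss_distance": int(signed)})
    annotated = pd.DataFrame(rows)
    if len(annotated) == 0:
        return annotated
    annotated = annotated.head(top_n)
    annotated = annotated.drop_duplicates(subset="gene_id", keep="first")
    return annotated.reset_index(drop=True)


# --------------------------------------------------------- set overlap


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    odds_ratio: float
    p: float


def topn_overlap(gene_set_a: set, gene_set_b: set, universe: set) -> OverlapResult:
    """One-sided Fisher exact test of overlap between two gene sets.

    p = P(overlap >= observed) under hypergeometric sampling from the
    universe; sets are intersected with the universe first.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    a = set(gene_set_a) & universe
    b = set(gene_set_b) & universe
    k = len(a & b)
    n_u = len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_u, len(a), len(b)))
    table = np.array([[k, len(a) - k],
                      [len(b) - k, n_u - len(a) - len(b) + k]], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return OverlapResult(len(a), len(b), k, n_u, float(odds), min(p, 1.0))


def topn_overlap_by_direction(
    annotated_dmrs: pd.DataFrame,
    expression: pd.DataFrame,
    universe: set,
    top_n: int = 1000,
) -> pd.DataFrame:
    """Directional top-N overlap: (methylation up/down) x (expression up/down).

    The methylation set for a direction is the gene set of the top-N
    best-ranked annotated DMRs with that direction; the expression set is
    the top-N smallest-p genes with the matching log2fc sign.
    """
    rows = []
    for mdir in ("up", "down"):
        mset = set(
            annotated_dmrs[annotated_dmrs["direction"] == mdir]
            .head(top_n)["gene_id"]
        )
        for edir in ("up", "down"):
            sign = 1 if edir == "up" else -1
            sub = expression[
                (np.sign(expression["log2fc"]) == sign) & expression["p"].notna()
            ].sort_values("p", kind="stable")
            eset = set(sub.head(top_n).index)
            res = topn_overlap(mset, eset, universe)
            rows.append({"meth_direction": mdir, "expr_direction": edir,
                         "n_meth": res.n_a, "n_expr": res.n_b,
                         "overlap": res.n_overlap, "p": res.p})
    return pd.DataFrame(rows)


# ------------------------------------------------------ metagene matrix


@dataclass
class MetaGeneMatrix:
    """Genes x position-bins matrix of median-normalized tag density.

    Columns run 5' flank, scaled gene body, 3' flank; rows follow the
    supplied gene order; minus-strand genes are flipped so 5' is always
    left. ``ceiling`` is the configured quantile of the normalized values,
    the color ceiling used when rendering.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    body_bins: int
    flank_bins: int
    flank_bp: int
    ceiling: float

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"flank5_{i}" for i in range(self.flank_bins)]
            + [f"body_{i}" for i in range(self.body_bins)]
            + [f"flank3_{i}" for i in range(self.flank_bins)]
        )
        return pd.DataFrame(self.matrix, index=pd.Index(self.gene_ids,
                                                        name="gene_id"), columns=cols)


def metagene_matrix(
    tags: TagSet,
    genes: list[GeneModel],
    body_bins: int = 50,
    flank_bp: int = 2000,
    flank_bins: int = 20,
    quantile: float = 0.80,
) -> MetaGeneMatrix:
    """Tag density per gene in fixed flanks and a length-scaled body.

    Density is tags per bin divided by bin width (tags/bp); the body is
    rescaled to ``body_bins`` regardless of gene length; flanks are fixed
    base pairs. The matrix is divided by its median positive value (an
    all-zero matrix stays zero rather than NaN).
    """
    if flank_bins > 0 and flank_bp <= 0:
        raise ValueError("flank_bp must be positive when flank_bins > 0")
    too_short = [g.gene_id for g in genes if g.length <= body_bins]
    if too_short:
        raise ValueError(
            f"{len(too_short)} gene(s) shorter than body_bins bp, "
            f"e.g. {too_short[:3]}"
        )
    n_cols = 2 * flank_bins + body_bins
    matrix = np.zeros((len(genes), n_cols))
    for i, g in enumerate(genes):
        chrom_len = tags.genome.length_of(g.chrom)
        pos = tags.positions_on(g.chrom)
        edges_parts = []
        if flank_bins:
            edges_parts.append(
                np.linspace(g.start - flank_bp, g.start, flank_bins + 1))
        edges_parts.append(np.linspace(g.start, g.end, body_bins + 1))
        if flank_bins:
            edges_parts.append(np.linspace(g.end, g.end + flank_bp, flank_bins + 1))
        edges = np.concatenate(
            [p if j == 0 else p[1:] for j, p in enumerate(edges_parts)])
        clipped = np.clip(edges, 0, chrom_len)  # flanks may run off the end
        counts = np.diff(np.searchsorted(pos, clipped))
        eff_width = np.diff(clipped)
        dens = np.where(eff_width > 0, counts / np.maximum(eff_width, 1e-9), 0.0)
        matrix[i] = dens[::-1] if g.strand == "-" else dens
    positive = matrix[matrix > 0]
    if positive.size:
        matrix = matrix / np.median(positive)
    ceiling = float(np.quantile(matrix, quantile)) if matrix.size else 0.0
    return MetaGeneMatrix(matrix, [g.gene_id for g in genes], body_bins,
                          flank_bins, flank_bp, ceiling)


def rank_intragenic_difference(
    matrix_a: MetaGeneMatrix,
    matrix_b: MetaGeneMatrix,
    top_n: int = 500,
) -> pd.DataFrame:
    """Rank genes by summed gene-body density gain, condition B minus A.

    Both matrices must share gene order and binning (each is already
    median-normalized at construction). The score is antisymmetric in
    (A, B); the sort is stable and descending, so identical matrices
    preserve input order with all-zero scores. ``in_top_n`` flags the
    requested head of the ranking.
    """
    if matrix_a.gene_ids != matrix_b.gene_ids or \
            matrix_a.matrix.shape != matrix_b.matrix.shape:
        raise ValueError("matrices must share gene order and binning")
    body = matrix_a.body_slice
    score = (matrix_b.matrix[:, body] - matrix_a.matrix[:, body]).sum(axis=1)
    df = pd.DataFrame({"gene_id": matrix_a.gene_ids, "score": score})
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["in_top_n"] = df["rank"] <= top_n
    return df


def decile_score_test(
    scores: pd.DataFrame,
    expression: pd.DataFrame,
    n_deciles: int = 10,
) -> tuple[float, float]:
    """Top- vs bottom-expression-decile test of intragenic scores.

    Genes are ordered by the signed expression Wald statistic; the
    intragenic 5hmC scores of the top decile are compared with the bottom
    decile by a one-sided Welch t-test (alternative: top > bottom).
    Returns (mean difference, p).
    """
    ranked = expression[expression["p"].notna()].sort_values(
        "stat", ascending=False, kind="stable")
    k = max(1, len(ranked) // n_deciles)
    top = set(ranked.head(k).index)
    bottom = set(ranked.tail(k).index)
    score_of = dict(zip(scores["gene_id"], scores["score"]))
    top_scores = np.array([score_of[g] for g in top if g in score_of])
    bot_scores = np.array([score_of[g] for g in bottom if g in score_of])
    if top_scores.size < 2 or bot_scores.size < 2:
        raise ValueError("too few genes per decile")
    res = stats.ttest_ind(top_scores, bot_scores, equal_var=False,
                          alternative="greater")
    return float(top_scores.mean() - bot_scores.mean()), float(res.pvalue)


def render_metagene_heatmap(matrix: MetaGeneMatrix, path: str) -> None:
    """Save the matrix as a heatmap clipped at the quantile ceiling."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    vmax = matrix.ceiling if matrix.ceiling > 0 else None
    ax.imshow(matrix.matrix, aspect="auto", cmap="viridis", vmin=0, vmax=vmax,
              interpolation="nearest")
    ax.axvline(matrix.flank_bins - 0.5, color="white", lw=0.8)
    ax.axvline(matrix.flank_bins + matrix.body_bins - 0.5, color="white", lw=0.8)
    ax.set_xlabel("5' flank | scaled gene body | 3' flank")
    ax.set_ylabel("genes (supplied order)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
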