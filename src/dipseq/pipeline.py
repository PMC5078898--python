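"""Stage orchestration: simulate -> segment -> diff-meth -> diff-expr ->
integrate -> enrich, with files as the interface between stages.

Each stage is callable standalone (partial reruns are cheap; the
permutation segmentation dominates runtime) and logs counts in/out of
every filter so attrition is auditable. ``run_all`` chains the stages and
writes a manifest capturing the config snapshot, input digests, seed and
per-stage outputs; re-running with the same seed reproduces identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, integration, io, segmentation
from .config import PipelineConfig
from .expression import test_expression
from .genome import Genome, TagSet
from .simulate import (CONDITION_A, CONDITION_B, SimParams, simulate_dataset,
                       write_truth)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    rng_seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict[str, int]] = field(default_factory=dict)

    def add_stage(self, name: str, outputs: dict[str, int]) -> None:
        self.stages[name] = outputs

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def merge_tagsets(tagsets: list[TagSet], sample_id: str) -> TagSet:
    """Pool libraries (e.g. replicates of one condition) into one TagSet."""
    genome = tagsets[0].genome
    positions: dict[str, list[np.ndarray]] = {}
    for ts in tagsets:
        for chrom in ts.chroms:
            positions.setdefault(chrom, []).append(ts.positions_on(chrom))
    merged = {c: np.concatenate(p) for c, p in positions.items()}
    return TagSet(sample_id, tagsets[0].assay, tagsets[0].condition, genome, merged)


# ------------------------------------------------------------------ stages


def stage_simulate(
    params: SimParams,
    out_dir: str | Path,
    seed: int | None = None,
    assays: tuple[str, ...] = ("5mC", "5hmC"),
) -> dict[str, int]:
    """Generate a dataset and serialize every piece as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(params, seed=seed, assays=assays)
    io.write_genome(ds.genome, out / "genome.tsv")
    io.write_gene_models(ds.genes, out / "genes.bed12")
    sample_rows = []
    for (assay, condition, pool), tags in ds.dip_tags.items():
        fname = f"tags_{assay}_{condition}_pool{pool}.bed"
        io.write_tags(tags, out / fname)
        sample_rows.append((fname, tags.sample_id, assay, condition, pool))
    pd.DataFrame(sample_rows, columns=["file", "sample_id", "assay",
                                       "condition", "pool"]).to_csv(
        out / "samples.tsv", sep="\t", index=False)
    io.write_counts(ds.rna_counts, out / "rna_counts.tsv")
    write_truth(ds.truth, out)
    params.to_yaml(out / "sim_params.yaml")
    _write_synthetic_categories(ds, out / "categories.tsv",
                                seed=params.rng_seed if seed is None else seed)
    return {
        "genes.bed12": len(ds.genes),
        "samples.tsv": len(sample_rows),
        "rna_counts.tsv": len(ds.rna_counts),
    }


def _write_synthetic_categories(ds, path: Path, seed: int, n_random: int = 20,
                                size: int = 100) -> None:
    """Category map for the enrichment stage: the planted coupled set plus
    random categories (synthetic stand-in for a real ontology)."""
    rng = np.random.default_rng(seed + 1)
    gene_ids = [g.gene_id for g in ds.genes]
    rows = [("coupled_truth", g) for g in ds.truth.coupled_genes]
    for i in range(n_random):
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        rows.extend((f"random_{i:02d}", g) for g in members)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def _ordered_conditions(values) -> list[str]:
    """Reference condition first: 'sham' (condition A) precedes any other
    label when present; otherwise lexicographic order."""
    uniq = sorted(set(map(str, values)))
    if CONDITION_A in uniq:
        return [CONDITION_A] + [c for c in uniq if c != CONDITION_A]
    return uniq


def _load_samples(data_dir: Path, genome: Genome) -> pd.DataFrame:
    samples = pd.read_csv(data_dir / "samples.tsv", sep="\t")
    samples["tags"] = [
        io.read_tags(data_dir / r.file, genome, r.assay, str(r.condition),
                     sample_id=r.sample_id)
        for r in samples.itertuples(index=False)
    ]
    return samples


def stage_segment(
    config: PipelineConfig,
    data_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, int]:
    """Call enriched domains per DIP sample."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = io.read_genome(data_dir / "genome.tsv")
    samples = _load_samples(data_dir, genome)
    outputs = {}
    for r in samples.itertuples(index=False):
        domains, _ = segmentation.segment(
            r.tags, genome, window_bp=config.window_bp, step_bp=config.step_bp,
            n_permutations=config.n_permutations, alpha=config.enrich_alpha,
            seed=seed,
        )
        fname = f"domains_{r.sample_id}.tsv"
        io.write_regions(segmentation.domains_to_frame(domains), out / fname)
        logger.info("segment %s: %d domains", r.sample_id, len(domains))
        outputs[fname] = len(domains)
    return outputs


def stage_diff_meth(
    config: PipelineConfig,
    data_dir: str | Path,
    seg_dir: str | Path,
    out_dir: str | Path,
) -> dict[str, int]:
    """Merge enrichment territory per assay and call DMRs."""
    data_dir, seg_dir, out = Path(data_dir), Path(seg_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = io.read_genome(data_dir / "genome.tsv")
    samples = _load_samples(data_dir, genome)
    outputs = {}
    for assay in sorted(samples["assay"].unique()):
        sub = samples[samples["assay"] == assay]
        domain_lists = [
            io.frame_to_intervals(io.read_regions(seg_dir / f"domains_{r.sample_id}.tsv"))
            for r in sub.itertuples(index=False)
        ]
        resolution = config.dmr_window_bp if config.dmr_unit == "tiles" else None
        regions = differential.merge_regions(domain_lists, resolution)
        conds = _ordered_conditions(sub["condition"])
        tags_a = list(sub[sub["condition"] == conds[0]]["tags"])
        tags_b = list(sub[sub["condition"] == conds[-1]]["tags"])
        tested = differential.test_regions(
            regions, tags_a, tags_b, assay=assay, test=config.dmr_test,
            diff_mode=config.dmr_diff_mode,
        )
        dmrs = differential.call_dmrs(tested, config.dmr_q_threshold,
                                      config.dmr_min_tag_diff)
        # persist the full tested table (with q) alongside the filtered DMRs
        full = differential.call_dmrs(tested, q_threshold=np.inf, min_tag_diff=-1.0) \
            if len(tested) else tested
        io.write_regions(full, out / f"tested_{assay}.tsv")
        io.write_regions(dmrs, out / f"dmrs_{assay}.tsv")
        logger.info("diff-meth %s: %d regions tested, %d DMRs", assay,
                    len(tested), len(dmrs))
        outputs[f"dmrs_{assay}.tsv"] = len(dmrs)
        outputs[f"tested_{assay}.tsv"] = len(tested)
    return outputs


def stage_diff_expr(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> dict[str, int]:
    """Differential expression from the counts table."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = io.read_counts(data_dir / "rna_counts.tsv")
    condition_of = {c: c.rsplit("_rep", 1)[0] for c in counts.columns}
    result = test_expression(counts, condition_of, condition_b=CONDITION_B
                             if CONDITION_B in condition_of.values() else None)
    result.to_csv(out / "expression.tsv", sep="\t")
    n_sig = int((result["storey_q"] < config.expression_q_threshold).sum())
    logger.info("diff-expr: %d/%d genes at q<%g", n_sig, len(result),
                config.expression_q_threshold)
    return {"expression.tsv": len(result)}


def stage_integrate(
    config: PipelineConfig,
    data_dir: str | Path,
    meth_dir: str | Path,
    expr_dir: str | Path,
    out_dir: str | Path,
    heatmaps: bool = False,
) -> dict[str, int]:
    """Annotate DMRs, overlap with expression, metagene matrices, ranking."""
    data_dir, meth_dir = Path(data_dir), Path(meth_dir)
    expr_dir, out = Path(expr_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = io.read_genome(data_dir / "genome.tsv")
    genes = io.read_gene_models(data_dir / "genes.bed12")
    samples = _load_samples(data_dir, genome)
    expr = pd.read_csv(expr_dir / "expression.tsv", sep="\t", index_col="gene_id")
    outputs = {}
    universe = set(g.gene_id for g in genes)
    for assay in sorted(samples["assay"].unique()):
        dmr_path = meth_dir / f"dmrs_{assay}.tsv"
        if not dmr_path.exists():
            continue
        dmrs = io.read_regions(dmr_path)
        annotated = integration.annotate_dmrs(
            dmrs, genes, max_dist_bp=config.tss_max_dist_bp,
            top_n=config.top_n_dmrs, anchor=config.tss_anchor)
        annotated.to_csv(out / f"annotated_dmrs_{assay}.tsv", sep="\t", index=False)
        outputs[f"annotated_dmrs_{assay}.tsv"] = len(annotated)
        if len(annotated):
            overlap = integration.topn_overlap_by_direction(
                annotated, expr, universe, top_n=config.top_n_overlap)
            overlap.to_csv(out / f"overlap_{assay}.tsv", sep="\t", index=False)
            outputs[f"overlap_{assay}.tsv"] = len(overlap)
        # metagene matrices per condition, genes ordered by expression stat
        ordered = expr.sort_values("stat", ascending=False, kind="stable")
        gene_by_id = {g.gene_id: g for g in genes}
        ordered_genes = [gene_by_id[g] for g in ordered.index if g in gene_by_id]
        sub = samples[samples["assay"] == assay]
        conds = _ordered_conditions(sub["condition"])
        mats = {}
        for cond in conds:
            pooled = merge_tagsets(list(sub[sub["condition"] == cond]["tags"]),
                                   f"{assay}_{cond}_pooled")
            mats[cond] = integration.metagene_matrix(
                pooled, ordered_genes, body_bins=config.metagene_body_bins,
                flank_bp=config.metagene_flank_bp,
                flank_bins=config.metagene_flank_bins,
                quantile=config.heatmap_quantile)
            mats[cond].to_frame().to_csv(
                out / f"metagene_{assay}_{cond}.tsv", sep="\t")
            if heatmaps:
                integration.render_metagene_heatmap(
                    mats[cond], str(out / f"metagene_{assay}_{cond}.png"))
        if len(conds) == 2:
            ranking = integration.rank_intragenic_difference(
                mats[conds[0]], mats[conds[-1]], top_n=config.top_n_intragenic)
            ranking.to_csv(out / f"intragenic_rank_{assay}.tsv", sep="\t",
                           index=False)
            outputs[f"intragenic_rank_{assay}.tsv"] = len(ranking)
    return outputs


def stage_enrich(
    config: PipelineConfig,
    data_dir: str | Path,
    integrate_dir: str | Path,
    expr_dir: str | Path,
    out_dir: str | Path,
) -> dict[str, int]:
    """Category enrichment of the DMR gene lists and the expression ranking."""
    data_dir, integrate_dir = Path(data_dir), Path(integrate_dir)
    expr_dir, out = Path(expr_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = io.read_gene_models(data_dir / "genes.bed12")
    categories = enrichment.read_category_map(data_dir / "categories.tsv")
    expr = pd.read_csv(expr_dir / "expression.tsv", sep="\t", index_col="gene_id")
    universe = set(g.gene_id for g in genes)
    weights = {g.gene_id: float(g.mappable_length) for g in genes}
    outputs = {}
    for path in sorted(integrate_dir.glob("annotated_dmrs_*.tsv")):
        assay = path.stem.replace("annotated_dmrs_", "")
        annotated = pd.read_csv(path, sep="\t")
        gene_set = set(annotated["gene_id"]) & universe if len(annotated) else set()
        fisher = enrichment.enrich_fisher(gene_set, categories, universe,
                                          config.enrichment_q_threshold)
        fisher.to_csv(out / f"enrich_fisher_{assay}.tsv", sep="\t", index=False)
        weighted = enrichment.enrich_weighted(gene_set, categories, universe,
                                              weights,
                                              config.enrichment_q_threshold)
        weighted.to_csv(out / f"enrich_weighted_{assay}.tsv", sep="\t", index=False)
        outputs[f"enrich_fisher_{assay}.tsv"] = len(fisher)
        outputs[f"enrich_weighted_{assay}.tsv"] = len(weighted)
    stat = expr.loc[expr["p"].notna(), "stat"]
    ks = enrichment.enrich_ks(stat, categories,
                              q_threshold=config.enrichment_q_threshold)
    ks.to_csv(out / "enrich_ks_expression.tsv", sep="\t", index=False)
    outputs["enrich_ks_expression.tsv"] = len(ks)
    return outputs


STAGE_ORDER = ("simulate", "segment", "diff_meth", "diff_expr",
               "integrate", "enrich")


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    sim_params: SimParams | None = None,
    data_dir: str | Path | None = None,
    seed: int | None = None,
    assays: tuple[str, ...] = ("5mC", "5hmC"),
    heatmaps: bool = False,
) -> RunManifest:
    """Run the whole pipeline; failures halt with the failing stage named.

    Either ``sim_params`` (synthetic run) or ``data_dir`` (pre-existing
    inputs from a simulate stage or equivalent files) must be provided.
    """
    config.validate()
    if sim_params is None and data_dir is None:
        raise ValueError("provide sim_params to simulate or data_dir with inputs")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    manifest = RunManifest(config=config.to_dict(), rng_seed=seed)
    data = Path(data_dir) if data_dir is not None else out / "data"
    stage_args = {
        "simulate": lambda: stage_simulate(sim_params, data, seed=seed,
                                           assays=assays),
        "segment": lambda: stage_segment(config, data, out / "segment", seed=seed),
        "diff_meth": lambda: stage_diff_meth(config, data, out / "segment",
                                             out / "diff_meth"),
        "diff_expr": lambda: stage_diff_expr(config, data, out / "diff_expr"),
        "integrate": lambda: stage_integrate(config, data, out / "diff_meth",
                                             out / "diff_expr", out / "integrate",
                                             heatmaps=heatmaps),
        "enrich": lambda: stage_enrich(config, data, out / "integrate",
                                       out / "diff_expr", out / "enrich"),
    }
    for stage in STAGE_ORDER:
        if stage == "simulate" and sim_params is None:
            continue
        try:
            manifest.add_stage(stage, stage_args[stage]())
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    for f in sorted(data.glob("*.tsv")):
        manifest.input_digests[f.name] = _digest(f)
    manifest.write(out / "manifest.json")
    return manifest
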