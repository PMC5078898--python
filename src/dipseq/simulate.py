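"""Synthetic DIP-Seq / RNA-Seq data with planted, recoverable truth.

The generator emulates the structure of a two-condition hippocampal
methylome study: a homogeneous Poisson tag background with planted
enriched domains (immunoprecipitation signal), a subset of domains whose
enrichment changes by a fold ratio between conditions (DMRs/DHRs),
negative-binomial RNA counts with a differentially expressed subset, and a
coupled subset of genes that jointly receive an intragenic 5hmC gain and
an expression gain — the configuration in which increased gene-body
hydroxymethylation accompanies transcriptional up-regulation.

Every stochastic choice flows from a single :class:`numpy.random.Generator`
so a seed reproduces the full dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, Genome, GenomicInterval, TagSet

CONDITION_A = "sham"
CONDITION_B = "irradiated"


@dataclass
class SimParams:
    """Generator settings; defaults are the standard study conditions."""

    # genome
    n_chroms: int = 1
    chrom_length_bp: int = 10_000_000
    # DIP background and planted domains
    background_rate: float = 0.01  # tags per bp per library
    n_domains: int = 200
    domain_length_bp: int = 1000
    domain_min_gap_bp: int = 2000
    enrichment_fold: float = 8.0
    # differential methylation
    n_dmrs: int = 100
    dmr_fold_ratio: float = 3.0
    dmr_up_fraction: float = 0.5
    n_pools: int = 2  # libraries per condition per assay
    library_size: int | None = None  # None: realized from rates
    # gene models
    n_genes: int = 2000
    gene_length_mean_bp: int = 2000
    gene_length_sigma: float = 0.35  # lognormal sd on log length
    gene_min_gap_bp: int = 500
    max_exons: int = 4
    exonic_fraction: float = 0.6
    # RNA counts
    rna_mean: float = 100.0
    rna_mean_sigma: float = 0.0  # lognormal sd of per-gene base mean
    rna_dispersion: float = 0.1
    n_de_genes: int = 300
    de_log2fc: float = 1.0
    n_replicates: int = 4
    depth_variation: float = 0.2  # lognormal sd of per-sample depth factor
    # methylation-expression coupling
    n_coupled_genes: int = 100
    coupled_body_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("chrom_length_bp", "background_rate", "enrichment_fold",
                     "dmr_fold_ratio", "rna_mean", "rna_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1 for planted domains")
        if self.n_dmrs > self.n_domains:
            raise ValueError("n_dmrs cannot exceed n_domains")
        if self.n_coupled_genes > self.n_de_genes:
            raise ValueError("coupled genes must be a subset of DE genes")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass(frozen=True)
class DomainTruth:
    interval: GenomicInterval
    fold: float
    assay: str


@dataclass(frozen=True)
class DmrTruth:
    interval: GenomicInterval
    assay: str
    direction: str  # "up"/"down" in condition B relative to A
    fold_ratio: float  # multiplier applied in condition B


@dataclass
class SimTruth:
    """Ground truth for recovery scoring."""

    planted_domains: list[DomainTruth] = field(default_factory=list)
    planted_dmrs: list[DmrTruth] = field(default_factory=list)
    de_genes: list[tuple[str, float]] = field(default_factory=list)  # (gene_id, log2fc)
    coupled_genes: list[str] = field(default_factory=list)
    gene_base_mean: dict[str, float] = field(default_factory=dict)

    def domain_intervals(self, assay: str) -> list[GenomicInterval]:
        return [d.interval for d in self.planted_domains if d.assay == assay]

    def dmr_intervals(self, assay: str) -> list[GenomicInterval]:
        return [d.interval for d in self.planted_dmrs if d.assay == assay]

    def de_lookup(self) -> dict[str, float]:
        return dict(self.de_genes)

    def validate(self, genome: Genome) -> None:
        for d in self.planted_domains:
            if d.interval.end > genome.length_of(d.interval.chrom):
                raise ValueError(f"planted domain {d.interval} outside genome")
        de = self.de_lookup()
        for g in self.coupled_genes:
            if de.get(g, 0.0) <= 0:
                raise ValueError(f"coupled gene {g} is not an up-regulated DE gene")


# ----------------------------------------------------------- genome/genes


def simulate_genome_and_genes(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[Genome, list[GeneModel]]:
    """Build a genome and pack non-overlapping gene models onto it.

    Genes are placed uniformly by distributing the leftover inter-gene
    space at random; lengths are lognormal around the configured mean.
    Raises if the requested genes cannot fit (suggesting a larger genome).
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    genome = Genome(
        {f"chr{i + 1}": params.chrom_length_bp for i in range(params.n_chroms)}
    )
    if params.n_genes == 0:
        return genome, []
    mu = np.log(params.gene_length_mean_bp)
    lengths = np.maximum(
        200,
        rng.lognormal(mu, params.gene_length_sigma, size=params.n_genes).astype(int),
    )
    spans = _pack_intervals(genome, lengths, params.gene_min_gap_bp, rng)
    genes = []
    for i, span in enumerate(spans):
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(span, params, rng)
        genes.append(
            GeneModel(f"gene{i:05d}", span.chrom, strand, span.start, span.end, exons)
        )
    return genome, genes


def _pack_intervals(
    genome: Genome, lengths: np.ndarray, min_gap: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    lengths = np.asarray(lengths, dtype=np.int64)
    order = rng.permutation(len(lengths))
    lengths = lengths[order]
    chrom_names = genome.chrom_names
    chrom_lens = np.array([genome.length_of(c) for c in chrom_names], dtype=float)
    # assign items to chromosomes proportional to length, retrying on overflow
    for _ in range(50):
        assign = rng.choice(len(chrom_names), size=len(lengths),
                            p=chrom_lens / chrom_lens.sum())
        ok = True
        for ci, name in enumerate(chrom_names):
            need = lengths[assign == ci]
            if need.sum() + max(0, need.size - 1) * min_gap > genome.length_of(name):
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError(
            "cannot pack intervals without overlap; increase the genome size"
        )
    out: list[GenomicInterval] = []
    for ci, name in enumerate(chrom_names):
        need = lengths[assign == ci]
        if need.size == 0:
            continue
        L = genome.length_of(name)
        free = L - int(need.sum()) - (need.size - 1) * min_gap
        extra = rng.multinomial(free, np.full(need.size + 1, 1.0 / (need.size + 1)))
        pos = 0
        for length, gap in zip(need, extra[:-1]):
            start = pos + int(gap)
            out.append(GenomicInterval(name, start, start + int(length)))
            pos = start + int(length) + min_gap
    return out


def _make_exons(
    span: GenomicInterval, params: SimParams, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    n_ex = int(rng.integers(1, params.max_exons + 1))
    if n_ex == 1 or span.length < 4 * n_ex:
        return (span,)
    exonic = max(n_ex, int(round(span.length * params.exonic_fraction)))
    intronic = span.length - exonic
    ex_sizes = 1 + rng.multinomial(exonic - n_ex, np.full(n_ex, 1.0 / n_ex))
    in_sizes = rng.multinomial(intronic, np.full(n_ex - 1, 1.0 / (n_ex - 1)))
    exons = []
    pos = span.start
    for i, size in enumerate(ex_sizes):
        exons.append(GenomicInterval(span.chrom, pos, pos + int(size)))
        if i < n_ex - 1:
            pos += int(size) + int(in_sizes[i])
    # pin last exon end to span end so tss/tes fall on exons
    last = exons[-1]
    exons[-1] = GenomicInterval(span.chrom, last.start, span.end)
    return tuple(exons)


# ------------------------------------------------------------ truth tables


def plant_truth(
    genome: Genome,
    genes: list[GeneModel],
    params: SimParams,
    rng: np.random.Generator | None = None,
    assays: tuple[str, ...] = ("5hmC",),
) -> SimTruth:
    """Choose planted domains, DMRs, DE genes and the coupled subset.

    Coupled genes receive an intragenic 5hmC domain that gains by the DMR
    fold ratio in condition B, alongside a positive expression log2fc, so
    downstream integration can recover the joint structure. Independent
    domains (and the DMR subset among them) are placed away from each other
    by at least ``domain_min_gap_bp``.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    truth = SimTruth()

    # DE genes: coupled ones first (all up), remainder split up/down.
    gene_ids = [g.gene_id for g in genes]
    if params.n_de_genes > len(gene_ids) and params.n_de_genes > 0:
        raise ValueError("n_de_genes exceeds the number of genes")
    de_ids = list(rng.choice(gene_ids, size=params.n_de_genes, replace=False)) \
        if params.n_de_genes else []
    coupled = de_ids[: params.n_coupled_genes]
    rest = de_ids[params.n_coupled_genes:]
    half = len(rest) // 2
    for gid in coupled:
        truth.de_genes.append((gid, params.de_log2fc))
    for gid in rest[:half]:
        truth.de_genes.append((gid, params.de_log2fc))
    for gid in rest[half:]:
        truth.de_genes.append((gid, -params.de_log2fc))
    truth.coupled_genes = list(coupled)

    # per-gene RNA base means, fixed across conditions
    if params.rna_mean_sigma > 0:
        means = rng.lognormal(np.log(params.rna_mean), params.rna_mean_sigma,
                              size=len(gene_ids))
    else:
        means = np.full(len(gene_ids), params.rna_mean)
    truth.gene_base_mean = {gid: float(m) for gid, m in zip(gene_ids, means)}

    gene_by_id = {g.gene_id: g for g in genes}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}

    # coupled intragenic 5hmC domains (gain in condition B)
    if "5hmC" in assays:
        for gid in coupled:
            g = gene_by_id[gid]
            dlen = max(200, int(g.length * params.coupled_body_fraction))
            dlen = min(dlen, g.length)
            start = g.start + (g.length - dlen) // 2
            iv = GenomicInterval(g.chrom, start, start + dlen)
            truth.planted_domains.append(
                DomainTruth(iv, params.enrichment_fold, "5hmC"))
            truth.planted_dmrs.append(
                DmrTruth(iv, "5hmC", "up", params.dmr_fold_ratio))
            occupied[g.chrom].append((start, start + dlen))

    # independent domains per assay, a subset of which are DMRs
    n_up = int(round(params.n_dmrs * params.dmr_up_fraction))
    for assay in assays:
        ivs = _place_avoiding(genome, occupied, params.n_domains,
                              params.domain_length_bp, params.domain_min_gap_bp, rng)
        dmr_idx = rng.choice(len(ivs), size=params.n_dmrs, replace=False) \
            if params.n_dmrs else np.empty(0, dtype=int)
        dmr_set = set(int(i) for i in dmr_idx)
        up_set = set(int(i) for i in list(dmr_idx)[:n_up])
        for i, iv in enumerate(ivs):
            truth.planted_domains.append(DomainTruth(iv, params.enrichment_fold, assay))
            if i in dmr_set:
                if i in up_set:
                    truth.planted_dmrs.append(
                        DmrTruth(iv, assay, "up", params.dmr_fold_ratio))
                else:
                    truth.planted_dmrs.append(
                        DmrTruth(iv, assay, "down", 1.0 / params.dmr_fold_ratio))
    truth.validate(genome)
    return truth


def _place_avoiding(
    genome: Genome,
    occupied: dict[str, list[tuple[int, int]]],
    n: int,
    length: int,
    min_gap: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Rejection-sample ``n`` disjoint intervals keeping ``min_gap`` from
    everything already placed (within and across calls)."""
    chroms = genome.chrom_names
    lens = np.array([genome.length_of(c) for c in chroms], dtype=float)
    out: list[GenomicInterval] = []
    tries = 0
    max_tries = 200 * max(n, 1)
    while len(out) < n:
        if tries > max_tries:
            raise ValueError("cannot place domains; increase the genome size")
        tries += 1
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        chrom = chroms[ci]
        L = genome.length_of(chrom)
        if L <= length:
            continue
        start = int(rng.integers(0, L - length))
        lo, hi = start - min_gap, start + length + min_gap
        if any(s < hi and lo < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


# --------------------------------------------------------------- DIP tags


def simulate_dip_tags(
    genome: Genome,
    truth: SimTruth,
    params: SimParams,
    condition: str,
    rng: np.random.Generator | None = None,
    assay: str = "5hmC",
    sample_id: str | None = None,
) -> TagSet:
    """Draw one DIP library: Poisson background plus planted enrichment.

    The per-bp rate is ``background_rate`` everywhere, multiplied by the
    domain fold inside planted domains, and additionally by the DMR fold
    ratio in condition B. If ``params.library_size`` is set, rates are
    rescaled so the expected total matches it; a zero library size yields
    an empty TagSet.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    sample_id = sample_id or f"{assay}_{condition}"
    if params.library_size == 0:
        return TagSet(sample_id, assay, condition, genome, {})

    dmr_map = {d.interval: d for d in truth.planted_dmrs if d.assay == assay}
    regions: list[tuple[GenomicInterval, float]] = []
    for dom in truth.planted_domains:
        if dom.assay != assay:
            continue
        fold = dom.fold
        dmr = dmr_map.get(dom.interval)
        if dmr is not None and condition == CONDITION_B:
            fold *= dmr.fold_ratio
        regions.append((dom.interval, fold))

    rate = params.background_rate
    if params.library_size is not None:
        expected = rate * genome.total_length + sum(
            rate * (f - 1.0) * iv.length for iv, f in regions if f > 1.0
        )
        rate *= params.library_size / expected

    positions: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        L = genome.length_of(chrom)
        n_bg = rng.poisson(rate * L)
        pos = rng.integers(0, L, size=n_bg)
        keep = np.ones(pos.size, dtype=bool)
        extras = []
        for iv, fold in regions:
            if iv.chrom != chrom:
                continue
            if fold >= 1.0:
                n_extra = rng.poisson(rate * (fold - 1.0) * iv.length)
                extras.append(rng.integers(iv.start, iv.end, size=n_extra))
            else:  # thin the background inside depleted regions
                inside = (pos >= iv.start) & (pos < iv.end)
                keep[inside] &= rng.random(int(inside.sum())) < fold
        parts = [pos[keep]] + extras
        positions[chrom] = np.concatenate(parts) if parts else np.empty(0, np.int64)
    return TagSet(sample_id, assay, condition, genome, positions)


# --------------------------------------------------------------- RNA counts


def simulate_rna_counts(
    genes: list[GeneModel],
    truth: SimTruth,
    params: SimParams,
    condition: str,
    n_replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Negative-binomial per-gene counts for one condition.

    Gene means are the base means from the truth table, scaled by
    ``2**log2fc`` in condition B for DE genes and by a per-replicate
    lognormal depth factor. The dispersion -> 0 limit reduces to Poisson.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    n_replicates = n_replicates or params.n_replicates
    de = truth.de_lookup()
    base = np.array([truth.gene_base_mean[g.gene_id] for g in genes])
    lfc = np.array([de.get(g.gene_id, 0.0) for g in genes])
    mean = base * np.power(2.0, lfc) if condition == CONDITION_B else base
    alpha = params.rna_dispersion
    cols = {}
    for j in range(n_replicates):
        depth = float(np.exp(rng.normal(0.0, params.depth_variation))) \
            if params.depth_variation > 0 else 1.0
        mu = mean * depth
        if alpha < 1e-10:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
            counts = rng.poisson(lam)
        cols[f"{condition}_rep{j + 1}"] = counts
    return pd.DataFrame(cols, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


# ------------------------------------------------------------- full dataset


@dataclass
class SimDataset:
    genome: Genome
    genes: list[GeneModel]
    truth: SimTruth
    params: SimParams
    dip_tags: dict[tuple[str, str, int], TagSet]  # (assay, condition, pool)
    rna_counts: pd.DataFrame  # genes x samples, both conditions
    condition_of: dict[str, str]  # sample column -> condition


def simulate_dataset(
    params: SimParams,
    seed: int | None = None,
    assays: tuple[str, ...] = ("5hmC",),
) -> SimDataset:
    """Generate a complete two-condition dataset with truth tables."""
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    genome, genes = simulate_genome_and_genes(params, rng)
    truth = plant_truth(genome, genes, params, rng, assays=assays)
    dip: dict[tuple[str, str, int], TagSet] = {}
    for assay in assays:
        for condition in (CONDITION_A, CONDITION_B):
            for pool in range(1, params.n_pools + 1):
                dip[(assay, condition, pool)] = simulate_dip_tags(
                    genome, truth, params, condition, rng, assay=assay,
                    sample_id=f"{assay}_{condition}_pool{pool}",
                )
    counts_a = simulate_rna_counts(genes, truth, params, CONDITION_A, rng=rng)
    counts_b = simulate_rna_counts(genes, truth, params, CONDITION_B, rng=rng)
    rna = pd.concat([counts_a, counts_b], axis=1)
    condition_of = {c: CONDITION_A for c in counts_a.columns}
    condition_of.update({c: CONDITION_B for c in counts_b.columns})
    return SimDataset(genome, genes, truth, params, dip, rna, condition_of)


def write_truth(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        [(d.interval.chrom, d.interval.start, d.interval.end, d.assay, d.fold)
         for d in truth.planted_domains],
        columns=["chrom", "start", "end", "assay", "fold"],
    ).to_csv(outdir / "truth_domains.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(d.interval.chrom, d.interval.start, d.interval.end, d.assay,
          d.direction, d.fold_ratio) for d in truth.planted_dmrs],
        columns=["chrom", "start", "end", "assay", "direction", "fold_ratio"],
    ).to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    de = pd.DataFrame(truth.de_genes, columns=["gene_id", "log2fc"])
    de["coupled"] = de["gene_id"].isin(set(truth.coupled_genes))
    de.to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
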