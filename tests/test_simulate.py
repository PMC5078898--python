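"""Synthetic-data generator: planted signal matches its stated rates."""

import numpy as np
import pytest

from dipseq import io
from dipseq.genome import GenomicInterval
from dipseq.simulate import (CONDITION_A, CONDITION_B, SimParams,
                             plant_truth, simulate_dataset,
                             simulate_dip_tags, simulate_genome_and_genes,
                             simulate_rna_counts)


def background_params(**kw):
    base = dict(n_genes=0, n_de_genes=0, n_coupled_genes=0, n_domains=0,
                n_dmrs=0, n_pools=1)
    base.update(kw)
    return SimParams(**base)


class TestGenomeAndGenePlacement:
    def test_genes_are_disjoint_by_construction(self, rng):
        p = SimParams(n_genes=200, gene_length_mean_bp=10_000,
                      gene_length_sigma=0.0, n_de_genes=0, n_coupled_genes=0)
        genome, genes = simulate_genome_and_genes(p, rng)
        assert len(genes) == 200
        spans = sorted((g.chrom, g.start, g.end) for g in genes)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_same_seed_reproduces_annotation(self):
        p = SimParams(n_genes=50, n_de_genes=0, n_coupled_genes=0)
        _, g1 = simulate_genome_and_genes(p, np.random.default_rng(9))
        _, g2 = simulate_genome_and_genes(p, np.random.default_rng(9))
        assert g1 == g2

    def test_infeasible_packing_raises(self, rng):
        p = SimParams(n_genes=200, gene_length_mean_bp=10_000,
                      gene_length_sigma=0.0, chrom_length_bp=10_000,
                      n_de_genes=0, n_coupled_genes=0)
        with pytest.raises(ValueError, match="genome"):
            simulate_genome_and_genes(p, rng)


class TestDipTags:
    def test_background_rate_uniform_without_domains(self):
        # fold 1 everywhere: window counts within 5 SD of the Poisson mean
        p = background_params()
        ds = simulate_dataset(p, seed=21)
        tags = ds.dip_tags[("5hmC", CONDITION_A, 1)]
        expected = p.background_rate * 100_000
        for start in range(0, 10_000_000, 1_000_000):
            n = tags.count_in(GenomicInterval("chr1", start, start + 100_000))
            assert abs(n - expected) < 5 * np.sqrt(expected)

    def test_planted_domain_rate_arithmetic(self):
        # one 1-kb domain at fold 8 over 0.01/bp: ~80 in-domain vs ~10/kb bg
        p = background_params(n_domains=1, chrom_length_bp=1_000_000)
        in_dom, bg = [], []
        for rep in range(100):
            ds = simulate_dataset(p, seed=500 + rep)
            (dom,) = ds.truth.domain_intervals("5hmC")
            tags = ds.dip_tags[("5hmC", CONDITION_A, 1)]
            in_dom.append(tags.count_in(dom))
            far = (dom.start + 500_000) % 999_000
            bg.append(tags.count_in(GenomicInterval("chr1", far, far + 1000)))
        assert np.mean(in_dom) == pytest.approx(80, abs=3)
        assert np.mean(bg) == pytest.approx(10, abs=1.5)

    def test_dmr_fold_ratio_applies_only_in_condition_b(self):
        p = background_params(n_domains=20, n_dmrs=20, dmr_up_fraction=1.0)
        ds = simulate_dataset(p, seed=31)
        a = ds.dip_tags[("5hmC", CONDITION_A, 1)]
        b = ds.dip_tags[("5hmC", CONDITION_B, 1)]
        dmrs = ds.truth.dmr_intervals("5hmC")
        ratio = sum(b.count_in(iv) for iv in dmrs) / \
            sum(a.count_in(iv) for iv in dmrs)
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_zero_library_size_gives_empty_tagset(self):
        p = background_params(library_size=0)
        genome, _ = simulate_genome_and_genes(p, np.random.default_rng(0))
        truth = plant_truth(genome, [], p, np.random.default_rng(0))
        tags = simulate_dip_tags(genome, truth, p, CONDITION_A,
                                 np.random.default_rng(0))
        assert tags.library_size == 0

    def test_library_size_scaling_hits_target(self):
        p = background_params(library_size=50_000)
        ds = simulate_dataset(p, seed=3)
        lib = ds.dip_tags[("5hmC", CONDITION_A, 1)].library_size
        assert lib == pytest.approx(50_000, rel=0.02)

    def test_rate_ratio_converges_to_fold_with_library_size(self):
        # empirical in-domain/background ratio approaches the planted fold
        errors = []
        for lib in (20_000, 100_000, 500_000):
            p = background_params(n_domains=100, library_size=lib)
            ds = simulate_dataset(p, seed=77)
            tags = ds.dip_tags[("5hmC", CONDITION_A, 1)]
            doms = ds.truth.domain_intervals("5hmC")
            dom_bp = sum(d.length for d in doms)
            in_dom = sum(tags.count_in(d) for d in doms)
            bg_bp = 10_000_000 - dom_bp
            bg_rate = (tags.library_size - in_dom) / bg_bp
            errors.append(abs(in_dom / dom_bp / bg_rate - 8.0))
        assert errors[-1] < errors[0]
        assert errors[-1] < 0.4


class TestRnaCounts:
    def test_null_log2fc_means_equal_in_expectation(self):
        p = SimParams(n_genes=300, n_de_genes=0, n_coupled_genes=0,
                      depth_variation=0.0)
        rng = np.random.default_rng(5)
        genome, genes = simulate_genome_and_genes(p, rng)
        truth = plant_truth(genome, genes, p, rng)
        ca = simulate_rna_counts(genes, truth, p, CONDITION_A, 8, rng)
        cb = simulate_rna_counts(genes, truth, p, CONDITION_B, 8, rng)
        assert ca.values.mean() == pytest.approx(cb.values.mean(), rel=0.05)

    def test_zero_dispersion_limit_is_poisson(self):
        p = SimParams(n_genes=1, n_de_genes=0, n_coupled_genes=0,
                      rna_dispersion=1e-12, depth_variation=0.0)
        rng = np.random.default_rng(6)
        genome, genes = simulate_genome_and_genes(p, rng)
        truth = plant_truth(genome, genes, p, rng)
        draws = simulate_rna_counts(genes, truth, p, CONDITION_A, 10_000, rng)
        x = draws.to_numpy().ravel()
        assert x.var() / x.mean() == pytest.approx(1.0, abs=0.05)

    def test_same_seed_reproduces_table(self):
        p = SimParams(n_genes=100, n_de_genes=30, n_coupled_genes=10)
        d1 = simulate_dataset(p, seed=8)
        d2 = simulate_dataset(p, seed=8)
        assert d1.rna_counts.equals(d2.rna_counts)


class TestTruthAndSerialization:
    def test_coupled_genes_are_upregulated_de_genes(self):
        ds = simulate_dataset(SimParams(n_genes=500, n_de_genes=100,
                                        n_coupled_genes=40), seed=9)
        de = ds.truth.de_lookup()
        assert len(ds.truth.coupled_genes) == 40
        assert all(de[g] > 0 for g in ds.truth.coupled_genes)

    def test_dataset_serializes_losslessly(self, tmp_path):
        ds = simulate_dataset(SimParams(n_genes=30, n_domains=10, n_dmrs=5,
                                        n_de_genes=10, n_coupled_genes=5),
                              seed=10)
        io.write_genome(ds.genome, tmp_path / "genome.tsv")
        io.write_gene_models(ds.genes, tmp_path / "genes.bed12")
        tags = ds.dip_tags[("5hmC", CONDITION_B, 1)]
        io.write_tags(tags, tmp_path / "tags.bed")
        io.write_counts(ds.rna_counts, tmp_path / "counts.tsv")
        genome = io.read_genome(tmp_path / "genome.tsv")
        assert genome == ds.genome
        genes = io.read_gene_models(tmp_path / "genes.bed12")
        assert sorted(genes, key=lambda g: g.gene_id) == \
            sorted(ds.genes, key=lambda g: g.gene_id)
        back = io.read_tags(tmp_path / "tags.bed", genome, tags.assay,
                            tags.condition)
        assert back.library_size == tags.library_size
        counts = io.read_counts(tmp_path / "counts.tsv")
        assert counts.equals(ds.rna_counts)
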