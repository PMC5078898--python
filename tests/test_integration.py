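"""TSS annotation, top-N overlap, metagene matrices, intragenic ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dipseq import integration as integ
from dipseq.genome import GeneModel, Genome, GenomicInterval, TagSet


def _dmr_row(chrom, start, end, q=0.001, p=0.0005, diff=100.0,
             direction="up", assay="5hmC"):
    return {"chrom": chrom, "start": start, "end": end, "assay": assay,
            "count_a": 10, "count_b": 110, "norm_diff": diff, "stat": 30.0,
            "p": p, "q": q, "direction": direction}


@pytest.fixture
def one_gene():
    return [GeneModel("geneA", "chr1", "+", 100_000, 110_000)]


class TestAnnotateDmrs:
    def test_upstream_dmr_gets_negative_distance(self, one_gene):
        dmrs = pd.DataFrame([_dmr_row("chr1", 89_500, 90_500)])
        out = integ.annotate_dmrs(dmrs, one_gene, max_dist_bp=50_000)
        assert out.iloc[0]["gene_id"] == "geneA"
        assert out.iloc[0]["tss_distance"] == -10_000

    def test_minus_strand_flips_distance_sign(self):
        genes = [GeneModel("geneB", "chr1", "-", 100_000, 110_000)]
        # midpoint 10 kb beyond the 3'->5' TSS at 109_999 is upstream
        dmrs = pd.DataFrame([_dmr_row("chr1", 119_500, 120_500)])
        out = integ.annotate_dmrs(dmrs, genes, max_dist_bp=50_000)
        assert out.iloc[0]["tss_distance"] == -(120_000 - 109_999)

    def test_dmr_beyond_distance_limit_excluded(self, one_gene):
        dmrs = pd.DataFrame([_dmr_row("chr1", 35_000, 45_000)])  # 60 kb away
        out = integ.annotate_dmrs(dmrs, one_gene, max_dist_bp=50_000)
        assert len(out) == 0

    def test_one_record_per_gene_keeps_best_ranked(self, one_gene):
        dmrs = pd.DataFrame([
            _dmr_row("chr1", 95_000, 96_000, q=0.005),
            _dmr_row("chr1", 98_000, 99_000, q=0.0001),
        ])
        out = integ.annotate_dmrs(dmrs, one_gene, max_dist_bp=50_000)
        assert len(out) == 1
        assert out.iloc[0]["q"] == 0.0001

    def test_equidistant_tie_breaks_to_smaller_gene_id(self):
        genes = [GeneModel("geneZ", "chr1", "+", 90_000, 95_000),
                 GeneModel("geneA", "chr1", "-", 100_001, 110_000)]
        # midpoint 95_000+... anchor 95_000? pick anchor equidistant
        dmrs = pd.DataFrame([_dmr_row("chr1", 94_500, 95_500)])
        # distances: geneZ tss 90_000 -> 5_000; geneA tss 109_999 -> 14_999
        out = integ.annotate_dmrs(dmrs, genes, max_dist_bp=50_000)
        assert out.iloc[0]["gene_id"] == "geneZ"

    def test_annotation_deterministic_under_shuffling(self, rng, one_gene):
        rows = [_dmr_row("chr1", 90_000 + i * 1000, 90_500 + i * 1000,
                         q=float(q), p=float(q) / 2)
                for i, q in enumerate(rng.uniform(size=30))]
        df = pd.DataFrame(rows)
        out1 = integ.annotate_dmrs(df, one_gene, max_dist_bp=50_000)
        out2 = integ.annotate_dmrs(df.sample(frac=1, random_state=1),
                                   one_gene, max_dist_bp=50_000)
        pd.testing.assert_frame_equal(out1, out2)


class TestTopnOverlap:
    def test_disjoint_sets_have_p_one(self):
        u = {f"g{i}" for i in range(100)}
        res = integ.topn_overlap({"g1"}, {"g2"}, u)
        assert res.p == 1.0 and res.n_overlap == 0

    def test_matches_direct_hypergeometric_summation(self):
        # overlap 100 between two 1000-sets in a 20000 universe
        N, na, nb, k = 20_000, 1000, 1000, 100
        u = {f"g{i}" for i in range(N)}
        a = {f"g{i}" for i in range(na)}
        b = {f"g{i}" for i in range(k)} | \
            {f"g{i}" for i in range(na, na + nb - k)}
        res = integ.topn_overlap(a, b, u)
        oracle = sum(
            math.comb(na, x) * math.comb(N - na, nb - x)
            for x in range(k, min(na, nb) + 1)
        ) / math.comb(N, nb)
        assert res.n_overlap == k
        assert abs(res.p - oracle) < 1e-10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            integ.topn_overlap(set(), set(), set())


class TestMetagene:
    def _uniform_tags(self, gene, density, rng):
        genome = Genome({gene.chrom: 1_000_000})
        n = int(density * (gene.length + 2 * 4000))
        pos = rng.integers(gene.start - 4000, gene.end + 4000, size=n)
        pos = np.clip(pos, 0, 999_999)
        return TagSet("t", "5hmC", "x", genome, {gene.chrom: pos})

    def test_uniform_coverage_gives_flat_body(self, rng):
        gene = GeneModel("g", "chr1", "+", 200_000, 210_000)
        tags = self._uniform_tags(gene, 2.0, rng)  # ~20k tags in the body
        mat = integ.metagene_matrix(tags, [gene], body_bins=10,
                                    flank_bp=2000, flank_bins=5)
        body = mat.matrix[0, mat.body_slice]
        # binomial sampling bound: ~2000 tags/bin, 3 sd spread stays under 1.2
        assert body.max() / body.min() <= 1.2

    def test_minus_strand_rows_are_flipped(self):
        genome = Genome({"chr1": 100_000})
        plus = GeneModel("gp", "chr1", "+", 40_000, 50_000)
        minus = GeneModel("gm", "chr1", "-", 40_000, 50_000)
        # tags piled at the genomic start of the span
        tags = TagSet("t", "5hmC", "x", genome,
                      {"chr1": np.full(100, 40_100)})
        m_plus = integ.metagene_matrix(tags, [plus], 10, 1000, 2)
        m_minus = integ.metagene_matrix(tags, [minus], 10, 1000, 2)
        assert np.allclose(m_plus.matrix[0], m_minus.matrix[0][::-1])
        assert m_plus.matrix[0, m_plus.body_slice][0] > 0
        assert m_minus.matrix[0, m_minus.body_slice][-1] > 0

    def test_all_zero_tags_give_zero_matrix_not_nan(self):
        genome = Genome({"chr1": 100_000})
        gene = GeneModel("g", "chr1", "+", 40_000, 50_000)
        tags = TagSet("t", "5hmC", "x", genome, {})
        mat = integ.metagene_matrix(tags, [gene], 10, 1000, 2)
        assert np.all(mat.matrix == 0) and not np.any(np.isnan(mat.matrix))

    def test_gene_shorter_than_body_bins_rejected(self):
        genome = Genome({"chr1": 100_000})
        gene = GeneModel("tiny", "chr1", "+", 10, 30)
        tags = TagSet("t", "5hmC", "x", genome, {})
        with pytest.raises(ValueError, match="shorter"):
            integ.metagene_matrix(tags, [gene], body_bins=50)

    def test_ceiling_is_the_configured_quantile(self, rng):
        gene = GeneModel("g", "chr1", "+", 200_000, 210_000)
        tags = self._uniform_tags(gene, 0.5, rng)
        mat = integ.metagene_matrix(tags, [gene], 20, 2000, 5, quantile=0.8)
        assert mat.ceiling == pytest.approx(np.quantile(mat.matrix, 0.8))


class TestIntragenicRanking:
    def _matrix(self, values, gene_ids):
        return integ.MetaGeneMatrix(np.asarray(values, dtype=float),
                                    gene_ids, body_bins=2, flank_bins=1,
                                    flank_bp=1000, ceiling=1.0)

    def test_identical_matrices_give_zero_scores_in_input_order(self):
        m = self._matrix([[1, 2, 3, 1], [4, 5, 6, 4]], ["a", "b"])
        out = integ.rank_intragenic_difference(m, m, top_n=1)
        assert (out["score"] == 0).all()
        assert list(out["gene_id"]) == ["a", "b"]

    def test_score_is_antisymmetric(self, rng):
        vals_a = rng.uniform(size=(5, 4))
        vals_b = rng.uniform(size=(5, 4))
        ids = [f"g{i}" for i in range(5)]
        ab = integ.rank_intragenic_difference(
            self._matrix(vals_a, ids), self._matrix(vals_b, ids))
        ba = integ.rank_intragenic_difference(
            self._matrix(vals_b, ids), self._matrix(vals_a, ids))
        sa = ab.set_index("gene_id")["score"]
        sb = ba.set_index("gene_id")["score"]
        assert np.allclose(sa, -sb.loc[sa.index])

    def test_mismatched_matrices_rejected(self):
        m1 = self._matrix([[1, 2, 3, 4]], ["a"])
        m2 = self._matrix([[1, 2, 3, 4]], ["b"])
        with pytest.raises(ValueError, match="share"):
            integ.rank_intragenic_difference(m1, m2)


class TestDecileContrast:
    def test_coupled_structure_separates_deciles(self):
        # the intragenic score of highly expressed genes is elevated only
        # when coupling is planted
        from dipseq.analyses import _coupling_params, _intragenic_ranking
        from dipseq.expression import test_expression as run_de
        from dipseq.simulate import (CONDITION_A, CONDITION_B,
                                     simulate_dataset)
        for coupled, expect_sig in ((True, True), (False, False)):
            params = _coupling_params(coupled)
            params.n_pools = 1
            params.n_genes = 2000
            params.n_coupled_genes = 50 if coupled else 0
            params.n_de_genes = 150
            params.chrom_length_bp = 12_000_000
            ds = simulate_dataset(params, seed=99)
            expr = run_de(ds.rna_counts, ds.condition_of,
                          condition_b=CONDITION_B)
            ranking = _intragenic_ranking(
                ds, [ds.dip_tags[("5hmC", CONDITION_A, 1)]],
                [ds.dip_tags[("5hmC", CONDITION_B, 1)]], expr)
            _, p = integ.decile_score_test(ranking, expr)
            assert (p < 0.01) == expect_sig
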