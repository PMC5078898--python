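"""Region merging, 2x2 and NB tests, DMR filters, overlap Venns."""

import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dipseq import differential as diff
from dipseq.genome import GenomicInterval


class TestMergeRegions:
    def test_union_of_overlapping_sample_domains(self):
        lists = [[GenomicInterval("chr1", 0, 1000)],
                 [GenomicInterval("chr1", 800, 2000)]]
        assert diff.merge_regions(lists, None) == \
            [GenomicInterval("chr1", 0, 2000)]

    def test_retiling_clips_final_tile(self):
        lists = [[GenomicInterval("chr1", 0, 12_000)]]
        tiles = diff.merge_regions(lists, 5000)
        assert tiles == [GenomicInterval("chr1", 0, 5000),
                         GenomicInterval("chr1", 5000, 10_000),
                         GenomicInterval("chr1", 10_000, 12_000)]

    def test_empty_inputs_give_empty_list(self):
        assert diff.merge_regions([[], []], 5000) == []


class TestChiSquare:
    def test_perfect_homogeneity_is_null(self):
        stat, p = diff.test_region_chisq(10, 10, 1000, 1000)
        assert stat == 0.0 and p == 1.0

    def test_both_zero_counts_give_p_one(self):
        assert diff.test_region_chisq(0, 0, 1000, 1000) == (0.0, 1.0)

    def test_agrees_with_fisher_exact_oracle(self):
        # hypergeometric enumeration oracle for the (30,970;5,995) table
        a, b, c, d = 30, 970, 5, 995
        N, K, n = a + b + c + d, a + c, a + b
        denom = math.comb(N, n)
        fisher_two = 0.0
        p_obs = math.comb(K, a) * math.comb(N - K, n - a) / denom
        for x in range(max(0, n - (N - K)), min(K, n) + 1):
            px = math.comb(K, x) * math.comb(N - K, n - x) / denom
            if px <= p_obs * (1 + 1e-9):
                fisher_two += px
        _, p_chi = diff.test_region_chisq(a, c, a + b, c + d)
        # chi-square approximates the exact test; ~10 % relative agreement
        assert p_chi == pytest.approx(fisher_two, rel=0.10)

    def test_statistic_scales_with_counts(self):
        _, p1 = diff.test_region_chisq(30, 15, 1000, 1000)
        _, p2 = diff.test_region_chisq(60, 30, 2000, 2000)
        assert p2 < p1

    def test_normalized_difference_rescales_to_reference_library(self):
        assert diff.normalized_difference(10, 40, 1000, 2000) == 10.0


class TestNegativeBinomial:
    def test_identical_replicates_are_null(self):
        stat, p = diff.test_region_nb([10, 12], [10, 12],
                                      [1000, 1000], [1000, 1000])
        assert p >= 0.5

    def test_all_zero_counts_give_p_one(self):
        assert diff.test_region_nb([0, 0], [0, 0], [100, 100], [100, 100]) \
            == (0.0, 1.0)

    def test_single_replicate_falls_back_to_chisq(self, caplog):
        with caplog.at_level(logging.WARNING, logger="dipseq.differential"):
            stat, p = diff.test_region_nb([30], [5], [1000], [1000])
        assert "falling back" in caplog.text
        assert (stat, p) == diff.test_region_chisq(30, 5, 1000, 1000)

    def test_zero_dispersion_limit_matches_poisson_oracle(self):
        # equal libraries, dispersion 0: the Wald z should match the
        # closed-form Poisson z = (ln kb - ln ka) / sqrt(1/ka + 1/kb)
        # built from the same condition totals
        ka, kb, n = 400, 520, 4
        counts_a = np.full(n, ka / n)
        counts_b = np.full(n, kb / n)
        libs = np.full(n, 1e6)
        stat, p = diff.test_region_nb(counts_a, counts_b, libs, libs,
                                      dispersion=1e-12)
        z_oracle = (np.log(kb) - np.log(ka)) / np.sqrt(1 / ka + 1 / kb)
        assert stat == pytest.approx(z_oracle, rel=0.02)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_oracle)), rel=0.1)

    def test_chisq_and_nb_rank_regions_consistently(self):
        # one replicate pool per condition: the two tests should order
        # regions the same way (Spearman >= 0.9)
        rng = np.random.default_rng(8)
        rows_chi, rows_nb = [], []
        lib = 200_000
        for _ in range(150):
            mu = rng.uniform(20, 300)
            fold = rng.uniform(0.3, 3.0)
            a = rng.poisson(mu * 2)
            b = rng.poisson(mu * fold * 2)
            _, p_chi = diff.test_region_chisq(a, b, 2 * lib, 2 * lib)
            _, p_nb = diff.test_region_nb(
                rng.multinomial(a, [0.5, 0.5]), rng.multinomial(b, [0.5, 0.5]),
                [lib, lib], [lib, lib])
            rows_chi.append(p_chi)
            rows_nb.append(p_nb)
        rho = stats.spearmanr(rows_chi, rows_nb).statistic
        assert rho >= 0.9


class TestCallDmrs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "count_a",
                                           "count_b", "norm_diff", "stat",
                                           "p", "assay"])

    def test_joint_q_and_difference_filter(self):
        rows = [("chr1", 0, 5000, 10, 80, 60.0, 50.0, 1e-9, "5hmC"),
                ("chr1", 5000, 10_000, 10, 32, 20.0, 40.0, 1e-8, "5hmC"),
                ("chr1", 10_000, 15_000, 50, 55, 4.0, 0.2, 0.7, "5hmC")]
        dmrs = diff.call_dmrs(self._table(rows), 0.01, 50.0)
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["direction"] == "up"
        assert dmrs.iloc[0]["start"] == 0

    def test_all_p_one_yields_no_dmrs(self):
        rows = [("chr1", i * 5000, (i + 1) * 5000, 5, 5, 100.0, 0.0, 1.0,
                 "5mC") for i in range(10)]
        assert len(diff.call_dmrs(self._table(rows), 0.01, 50.0)) == 0

    def test_empty_input_gives_empty_output(self):
        out = diff.call_dmrs(self._table([]), 0.01, 50.0)
        assert len(out) == 0 and "q" in out.columns

    def test_bh_qvalues_monotone_in_p(self, rng):
        rows = [("chr1", i * 5000, (i + 1) * 5000, 5, 5, 100.0, 0.0,
                 float(p), "5mC") for i, p in enumerate(rng.uniform(size=200))]
        out = diff.call_dmrs(self._table(rows), np.inf, -1.0)
        srt = out.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
        assert ((srt["q"] > 0) & (srt["q"] <= 1)).all()


class TestDmrVenn:
    def test_disjoint_sets_have_p_one(self):
        res = diff.dmr_venn({"a": {"g1", "g2"}, "b": {"g3"}}, universe=10)
        assert res.iloc[0]["overlap"] == 0
        assert res.iloc[0]["p"] == 1.0

    def test_identical_sets_match_combinatorial_oracle(self):
        # P(full overlap of two fixed k-sets in universe N) = 1/C(N,k)
        k, N = 4, 12
        s = {f"g{i}" for i in range(k)}
        res = diff.dmr_venn({"a": set(s), "b": set(s)}, universe=N)
        assert res.iloc[0]["p"] == pytest.approx(1 / math.comb(N, k), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            diff.dmr_venn({"a": set()}, universe=0)

    def test_planted_shared_regions_are_detected(self, rng):
        # two assays called on overlapping planted gene sets
        shared = {f"g{i}" for i in range(40)}
        a = shared | {f"a{i}" for i in range(60)}
        b = shared | {f"b{i}" for i in range(60)}
        res = diff.dmr_venn({"5mC_up": a, "5hmC_up": b}, universe=5000)
        assert res.iloc[0]["p"] < 1e-6


def test_interval_overlap_counting():
    a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600),
         GenomicInterval("chr2", 0, 50)]
    b = [GenomicInterval("chr1", 90, 120), GenomicInterval("chr2", 100, 200)]
    assert diff.count_interval_overlaps(a, b) == 1
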