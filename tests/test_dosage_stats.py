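import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xdosage import dosage_stats as ds
from xdosage.io_core import ValidationError

from conftest import build_table


def ratios_df(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame({"log2_ratio": values,
                         "se": 0.0, "ci_low": values, "ci_high": values,
                         "n_a": 3, "n_b": 3}, index=pd.Index(genes))


class TestComputeLog2Ratios:
    def test_no_variance_ratio_and_zero_width_ci(self):
        a = build_table([[4.0, 4.0, 4.0]])
        b = build_table([[2.0, 2.0, 2.0]])
        r = ds.compute_log2_ratios(a, b)
        assert r.loc["g0", "log2_ratio"] == pytest.approx(1.0)
        assert r.loc["g0", "ci_high"] - r.loc["g0", "ci_low"] == pytest.approx(0.0)

    def test_equal_tables_give_zero(self):
        a = build_table([[3.0, 5.0, 4.0], [1.5, 2.0, 2.5]])
        r = ds.compute_log2_ratios(a, a)
        np.testing.assert_allclose(r["log2_ratio"], 0.0, atol=1e-12)

    def test_zero_value_rejected(self):
        a = build_table([[0.0, 1.0]])
        with pytest.raises(ValidationError, match="zero"):
            ds.compute_log2_ratios(a, a)

    @given(st.floats(min_value=0.01, max_value=100))
    def test_scaling_equivariance(self, c):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(1, 0.5, size=(8, 3))
        a, b = build_table(vals), build_table(rng.lognormal(1, 0.5, (8, 3)))
        r1 = ds.compute_log2_ratios(a, b)
        r2 = ds.compute_log2_ratios(build_table(vals * c), b)
        np.testing.assert_allclose(r2["log2_ratio"] - r1["log2_ratio"],
                                   np.log2(c), atol=1e-9)

    def test_single_replicate_side_has_nan_ci(self):
        a = build_table([[4.0]])
        b = build_table([[2.0, 2.0, 2.0]])
        r = ds.compute_log2_ratios(a, b)
        assert r.loc["g0", "log2_ratio"] == pytest.approx(1.0)
        assert np.isnan(r.loc["g0", "ci_low"])


class TestChromosomeSummary:
    def test_median_and_counts(self, toy_catalog):
        r = ratios_df([0.1, 0.3, 0.2, 0.4, 0.1, 0.3],
                      genes=list(toy_catalog.index))
        s = ds.chromosome_summary(r, toy_catalog)
        assert s.loc["I", "median"] == pytest.approx(0.2)  # even-count midpoint
        assert s.loc["X", "n"] == 2

    def test_single_gene_median_is_its_ratio(self, toy_catalog):
        r = ratios_df([0.7], genes=["g4"])
        s = ds.chromosome_summary(r, toy_catalog)
        assert s.loc["X", "median"] == pytest.approx(0.7)
        assert "I" not in s.index

    def test_unresolvable_gene_rejected(self, toy_catalog):
        with pytest.raises(ValidationError, match="catalog"):
            ds.chromosome_summary(ratios_df([0.1], genes=["nope"]), toy_catalog)


class TestRankSum:
    def test_separated_groups_exact_p(self):
        w, p = ds.rank_sum_test([4, 5, 6], [1, 2, 3], "greater")
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_identical_groups_two_sided_p_one(self):
        _, p = ds.rank_sum_test([1, 2, 3], [1, 2, 3], "two_sided")
        assert p == pytest.approx(1.0)

    def test_single_observations_wrong_direction(self):
        _, p = ds.rank_sum_test([1], [2], "greater")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_agrees_with_enumeration_oracle_including_ties(self, alternative):
        rng = np.random.default_rng(7)
        for n, m in [(2, 3), (3, 3), (4, 2), (5, 5), (4, 6)]:
            for _ in range(3):
                x = rng.integers(0, 5, n).astype(float)  # many ties
                y = rng.integers(0, 5, m).astype(float)
                _, p = ds.rank_sum_test(x, y, alternative)
                oracle = ds.brute_force_rank_sum_p(x, y, alternative)
                assert p == pytest.approx(oracle, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            ds.rank_sum_test([], [1.0])


class TestXvsAutosome:
    def test_reports_each_autosome_and_pooled(self, toy_catalog):
        r = ratios_df([0.0, 0.05, -0.05, 0.02, 0.5, 0.6],
                      genes=list(toy_catalog.index))
        out = ds.x_vs_autosome_test(r, toy_catalog, "greater")
        assert set(out.index) == {"I", "II", "pooled"}
        # X above everything: p = 1/C(4,2) = 1/6 per autosome
        assert out.loc["I", "p"] == pytest.approx(1 / 6)
        assert out.loc["pooled", "p"] == pytest.approx(1 / 15)

    def test_no_x_genes_rejected(self, toy_catalog):
        r = ratios_df([0.1, 0.2], genes=["g0", "g1"])
        with pytest.raises(ValidationError, match="X"):
            ds.x_vs_autosome_test(r, toy_catalog)


class TestFisherEnrichment:
    def test_tail_sum_matches_oracle(self):
        # X: 8/10 up; elsewhere 2/10 up
        p = ds.hypergeom_enrichment_p(8, 10, 10, 20)
        assert p == pytest.approx(ds.brute_force_hypergeom_p(8, 10, 10, 20),
                                  rel=1e-12)

    def test_equal_proportions_p_one(self):
        assert ds.hypergeom_enrichment_p(0, 10, 0, 20) == pytest.approx(1.0)

    def test_chromosome_table(self, toy_catalog):
        flags = pd.Series(["up", "up", "ns", "ns", "up", "ns"],
                          index=toy_catalog.index)
        out = ds.chromosome_enrichment_test(flags, toy_catalog)
        assert set(out.index) == {"I", "II", "X"}
        assert out.loc["I", "n_up"] == 2
        assert out.loc["I", "p_up"] == pytest.approx(
            ds.brute_force_hypergeom_p(2, 2, 3, 6), rel=1e-12)

    def test_unknown_flag_rejected(self, toy_catalog):
        flags = pd.Series(["sideways"] * 6, index=toy_catalog.index)
        with pytest.raises(ValidationError):
            ds.chromosome_enrichment_test(flags, toy_catalog)


class TestStageDynamics:
    def test_difference_and_antisymmetry(self):
        older = ratios_df([0.1, 0.4], genes=["a", "b"])
        younger = ratios_df([0.2, 0.1], genes=["a", "b"])
        d1, n1 = ds.change_in_compensation(older, younger)
        d2, _ = ds.change_in_compensation(younger, older)
        assert d1["a"] == pytest.approx(-0.1)
        assert n1 == 0
        np.testing.assert_allclose(d1, -d2)

    def test_exclusive_genes_counted(self):
        older = ratios_df([0.1, 0.2], genes=["a", "only_old"])
        younger = ratios_df([0.1], genes=["a"])
        d, n_excluded = ds.change_in_compensation(older, younger)
        assert list(d.index) == ["a"]
        assert n_excluded == 1

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ValidationError):
            ds.change_in_compensation(ratios_df([0.1], genes=["a"]),
                                      ratios_df([0.1], genes=["b"]))


class TestMaternalOverlap:
    def test_fraction_and_strict_threshold(self, toy_catalog):
        oocyte = pd.Series({"g4": 5.0, "g5": 1.0,   # exactly 1 -> not loaded
                            "g0": 0.5, "g1": 2.0})
        out = ds.maternal_overlap(["g0", "g1", "g4", "g5"], oocyte, toy_catalog)
        assert out.loc["X", "n_loaded"] == 1
        assert out.loc["X", "fraction_loaded"] == pytest.approx(0.5)
        assert out.loc["I", "fraction_loaded"] == pytest.approx(0.5)

    def test_missing_oocyte_value_reported(self, toy_catalog):
        oocyte = pd.Series({"g4": 5.0})
        out = ds.maternal_overlap(["g4", "g5"], oocyte, toy_catalog)
        assert out.loc["X", "n_missing"] == 1
        assert out.loc["X", "n_assessed"] == 1
        assert out.loc["X", "fraction_loaded"] == pytest.approx(1.0)


class TestSingleSexInference:
    def test_mixing_identity_cases(self):
        assert ds.estimate_single_sex_expression(1.0, 1.0)[0] == pytest.approx(1.0)
        # the published 11.2-fold mixed/herm ratio under an equal mix
        male, clamped = ds.estimate_single_sex_expression(1.0, 11.2)
        assert male == pytest.approx(21.4)
        assert not clamped
        assert ds.estimate_single_sex_expression(3.0, 7.0, male_fraction=1.0)[0] \
            == pytest.approx(7.0)

    def test_negative_inference_clamped_and_flagged(self):
        male, clamped = ds.estimate_single_sex_expression(10.0, 1.0)
        assert male == 0.0 and clamped

    def test_zero_male_fraction_rejected(self):
        with pytest.raises(ValueError):
            ds.estimate_single_sex_expression(1.0, 1.0, male_fraction=0.0)


class TestTopFractionRegulated:
    def test_exact_count_and_membership(self, toy_catalog):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 100)
        genes = [f"g{i:03d}" for i in range(100)]
        cat = pd.DataFrame({"chromosome": ["I"] * 100, "start": 1, "end": 10,
                            "strand": "+"}, index=pd.Index(genes, name="gene_id"))
        top, _ = ds.top_fraction_regulated(ratios_df(vals, genes), cat, 0.05)
        assert len(top) == 5
        expected = set(np.array(genes)[np.argsort(-np.abs(vals))[:5]])
        assert set(top) == expected

    def test_fraction_up_per_chromosome(self, toy_catalog):
        r = ratios_df([5.0, 4.0, 0.1, 0.1, 3.0, -2.0],
                      genes=list(toy_catalog.index))
        top, per_chrom = ds.top_fraction_regulated(r, toy_catalog, 0.60)
        assert per_chrom.loc["X", "fraction_up"] == pytest.approx(0.5)
        assert per_chrom.loc["I", "fraction_up"] == pytest.approx(1.0)

    def test_tie_at_cutoff_breaks_by_gene_id(self, toy_catalog):
        r = ratios_df([1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                      genes=list(toy_catalog.index))
        top1, _ = ds.top_fraction_regulated(r, toy_catalog, 0.5)
        top2, _ = ds.top_fraction_regulated(
            r.iloc[::-1], toy_catalog, 0.5)  # reversed input order
        assert list(top1) == ["g0", "g1", "g2"]
        assert list(top1) == list(top2)
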