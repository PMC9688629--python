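"""Permutation inference, maximal-statistic correction, ANOVA, Tukey."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cohnet import stats as st
from cohnet import synthetic as sd


class TestPermutationMeanDifference:
    def test_constant_groups_give_p_one(self):
        res = st.permutation_mean_difference([5.0] * 6, [5.0] * 6,
                                             n_perm=2000, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_extreme_separation_exhaustive_p(self):
        res = st.permutation_mean_difference([10.0] * 6, [0.0] * 6,
                                             n_perm=2000, tail="one", seed=0)
        assert res.exhaustive
        assert res.n_permutations == 924
        assert res.p_value == pytest.approx(1 / 924)

    def test_exhaustive_and_sampled_agree_on_small_inputs(self, rng):
        a = rng.normal(0.6, 1, 6)
        b = rng.normal(0.0, 1, 6)
        exact = st.permutation_mean_difference(a, b, n_perm=2000, seed=0)
        assert exact.exhaustive
        sampled = st.permutation_mean_difference(a, b, n_perm=600, seed=1)
        assert not sampled.exhaustive
        # Monte-Carlo binomial error bound (3 sigma) plus add-one offset
        p = exact.p_value
        assert abs(exact.p_value - sampled.p_value) < \
            3 * np.sqrt(p * (1 - p) / 600) + 2 / 600

    def test_two_tailed_doubles_symmetric_evidence(self, rng):
        a = rng.normal(1.0, 1, 8)
        b = rng.normal(0.0, 1, 8)
        one = st.permutation_mean_difference(a, b, n_perm=12870, tail="one")
        two = st.permutation_mean_difference(a, b, n_perm=12870, tail="two")
        assert one.exhaustive and two.exhaustive
        assert two.p_value >= one.p_value

    def test_both_one_sided_p_values_reported(self, rng):
        a = rng.normal(0.0, 1, 10)
        b = rng.normal(2.0, 1, 10)
        res = st.permutation_mean_difference(a, b, n_perm=500, tail="one",
                                             seed=2)
        assert res.observed < 0
        # fixed upper tail: a < b gives a large p_upper, small p_lower
        assert res.p_value == res.p_upper
        assert res.p_upper > 0.9
        assert res.p_lower < 0.1
        assert res.null_quantile_95 > 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.permutation_mean_difference([], [1.0], n_perm=10)

    def test_sampled_p_uses_add_one_rule(self, rng):
        a = rng.normal(5.0, 0.1, 20)
        b = rng.normal(0.0, 0.1, 20)
        res = st.permutation_mean_difference(a, b, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_p_values_are_calibrated(self):
        """Under H0, one-tailed p-values are uniform on the discrete
        permutation grid (Kolmogorov-Smirnov sanity check)."""
        rng = np.random.default_rng(2024)
        pvals = np.empty(1000)
        for r in range(1000):
            a = rng.standard_normal(4)
            b = rng.standard_normal(4)
            pvals[r] = st.permutation_mean_difference(
                a, b, n_perm=100, tail="one", seed=r).p_value
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestMaximalStatistic:
    def _matrices(self, rng, k, n, shift=0.0, edge=None):
        out = []
        for _ in range(k):
            m = rng.normal(0, 1, (n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            if edge is not None:
                i, j = edge
                m[i, j] += shift
                m[j, i] = m[i, j]
            out.append(m)
        return out

    def test_detects_injected_edge_with_positive_sign(self, rng):
        a = self._matrices(rng, 10, 12, shift=3.0, edge=(2, 5))
        b = self._matrices(rng, 10, 12)
        res = st.maximal_statistic_edge_test(a, b, n_perm=500, seed=0)
        sig = {(i, j): s for i, j, s in res.significant_edges}
        assert sig.get((2, 5)) == 1

    def test_t_map_symmetric_and_threshold_positive(self, rng):
        a = self._matrices(rng, 5, 8)
        b = self._matrices(rng, 5, 8)
        res = st.maximal_statistic_edge_test(a, b, n_perm=200, seed=1)
        np.testing.assert_allclose(res.t_map, res.t_map.T, atol=1e-12)
        assert res.corrected_threshold > 0
        assert len(res.max_null) == 200
        for i, j, _ in res.significant_edges:
            assert abs(res.t_map[i, j]) > res.corrected_threshold

    def test_single_edge_reduces_to_uncorrected_threshold(self, rng):
        # with one edge the max statistic IS the edge statistic
        a = self._matrices(rng, 6, 2)
        b = self._matrices(rng, 6, 2)
        res = st.maximal_statistic_edge_test(a, b, n_perm=300, seed=3)
        assert res.corrected_threshold == pytest.approx(
            np.percentile(res.max_null, 95))
        assert res.max_null.min() >= 0

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            st.maximal_statistic_edge_test(self._matrices(rng, 1, 4),
                                           self._matrices(rng, 4, 4))


class TestBonferroni:
    def test_examples(self):
        assert st.bonferroni_adjust([0.0005], 84)[0] == pytest.approx(0.042)
        assert st.bonferroni_adjust([0.5], 84)[0] == 1.0
        np.testing.assert_array_equal(st.bonferroni_adjust([0.1, 0.2], 1),
                                      [0.1, 0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bonferroni_adjust([1.5], 2)


class TestAnova:
    def test_degrees_of_freedom_for_12_by_5_design(self):
        recs = sd.generate_behavior(sd.ExperimentDesign(), seed=0)
        anova = st.anova_randomized_block(recs, "force_N")
        assert list(anova["df"]) == [11, 4, 44, 59]

    def test_sums_of_squares_decompose(self):
        recs = sd.generate_behavior(sd.ExperimentDesign(), seed=1)
        anova = st.anova_randomized_block(recs, "rppc")
        ss = anova.set_index("source")["ss"]
        assert ss["participant"] + ss["level"] + ss["error"] == \
            pytest.approx(ss["total"], abs=1e-9)

    def test_matches_statsmodels_oracle(self, rng):
        """Independent reference: OLS two-way additive ANOVA on a random
        balanced 4 subjects x 3 levels table."""
        import statsmodels.api as smapi
        from statsmodels.formula.api import ols
        df = pd.DataFrame(
            [{"subject": s, "level": f"L{l}", "trial": 0,
              "force_N": rng.normal(10 * l, 2)}
             for s in range(4) for l in range(3)])
        ours = st.anova_randomized_block(df, "force_N").set_index("source")
        fit = ols("force_N ~ C(subject) + C(level)", data=df).fit()
        ref = smapi.stats.anova_lm(fit, typ=2)
        assert ours.loc["participant", "ss"] == pytest.approx(
            ref.loc["C(subject)", "sum_sq"], abs=1e-9)
        assert ours.loc["level", "ss"] == pytest.approx(
            ref.loc["C(level)", "sum_sq"], abs=1e-9)
        assert ours.loc["error", "ss"] == pytest.approx(
            ref.loc["Residual", "sum_sq"], abs=1e-9)
        assert ours.loc["level", "F"] == pytest.approx(
            ref.loc["C(level)", "F"], rel=1e-9)

    def test_missing_cell_rejected(self):
        df = pd.DataFrame({"subject": [0, 0, 1], "level": ["a", "b", "a"],
                           "trial": 0, "force_N": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="balanced"):
            st.anova_randomized_block(df, "force_N")


class TestTukey:
    def test_standard_error_matches_published_force_table(self):
        tk = st.tukey_hsd(st.REFERENCE_FORCE_MEANS,
                          mse=st.REFERENCE_FORCE_ANOVA["ms_error"],
                          df_error=44, n_per_group=12)
        assert tk.se == pytest.approx(6.52, abs=0.005)
        row = tk.table.set_index("pair").loc["extremely_light-extremely_hard"]
        assert row["diff"] == pytest.approx(-59.31, abs=1e-9)
        assert row["t"] == pytest.approx(-9.09, abs=0.005)
        assert row["ci_lo"] == pytest.approx(-77.85, abs=0.03)
        assert row["ci_hi"] == pytest.approx(-40.76, abs=0.03)

    def test_force_grouping_letters(self):
        tk = st.tukey_hsd(st.REFERENCE_FORCE_MEANS,
                          mse=st.REFERENCE_FORCE_ANOVA["ms_error"],
                          df_error=44, n_per_group=12)
        g = tk.grouping_letters
        assert g["extremely_hard"] == "A"
        assert g["hard"] == g["somewhat_hard"] == "B"
        assert g["light"] == g["extremely_light"] == "C"

    def test_ci_half_width_is_q_over_sqrt2_times_se(self):
        tk = st.tukey_hsd({"a": 0.0, "b": 1.0, "c": 2.0}, mse=2.0,
                          df_error=10, n_per_group=4)
        half = tk.q_critical / np.sqrt(2) * tk.se
        row = tk.table.iloc[0]
        assert row["ci_hi"] - row["diff"] == pytest.approx(half, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.tukey_hsd({"a": 1.0, "b": 2.0}, mse=0.0, df_error=10,
                         n_per_group=3)
        with pytest.raises(ValueError):
            st.tukey_hsd({"a": 1.0, "b": 2.0}, mse=1.0, df_error=0,
                         n_per_group=3)


class TestPercentMvc:
    @pytest.mark.parametrize("force, mvc, expected",
                             [(57.5, 115.0, 50.0), (0.0, 115.0, 0.0),
                              (115.0, 115.0, 100.0)])
    def test_examples(self, force, mvc, expected):
        assert st.percent_mvc(force, mvc) == expected

    def test_invalid_mvc_rejected(self):
        with pytest.raises(ValueError):
            st.percent_mvc(10.0, 0.0)


class TestCompareNetworkMetrics:
    def _table(self, rng, effect=0.0):
        rows = []
        for band in ("alpha", "beta"):
            for metric in ("clustering_C", "efficiency_global_Eg"):
                for s in (0.1, 0.2):
                    for subj in range(8):
                        for lv, shift in (("extremely_light", 0.0),
                                          ("extremely_hard", effect)):
                            rows.append(dict(subject=subj, level=lv,
                                             band=band, sparsity=s,
                                             metric=metric,
                                             value=rng.normal(shift, 1)))
        return pd.DataFrame(rows)

    def test_row_count_bookkeeping(self, rng):
        out = st.compare_network_metrics(
            self._table(rng), ("extremely_hard", "extremely_light"),
            n_perm=200, seed=0)
        assert len(out) == 2 * 2 * 2  # bands x metrics x sparsities

    def test_detects_large_injected_effect(self, rng):
        out = st.compare_network_metrics(
            self._table(rng, effect=3.0),
            ("extremely_hard", "extremely_light"), n_perm=2000, seed=0)
        assert out["significant"].all()
        assert (out["observed"] > 0).all()

    def test_nodal_comparison_applies_bonferroni(self, rng):
        rows = [dict(subject=s, level=lv, band="alpha", sparsity=0.2,
                     metric="degree", node=n, value=rng.normal())
                for s in range(6) for lv in ("a", "b") for n in range(5)]
        out = st.compare_network_metrics(pd.DataFrame(rows), ("a", "b"),
                                         n_perm=200, seed=1)
        assert "p_adj" in out.columns
        np.testing.assert_allclose(out["p_adj"],
                                   np.minimum(1.0, 5 * out["p"]))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            st.compare_network_metrics(pd.DataFrame(), ("a", "b"))
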