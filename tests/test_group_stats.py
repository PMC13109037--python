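"""Rank statistics, effect sizes, FDR, ANCOVA, and partial correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from idscn import (
    ancova_group_age,
    bh_fdr_adjust,
    boxplot_outlier_mask,
    cliffs_delta,
    compare_groups_table,
    mann_whitney_test,
    partial_spearman,
    tiedrank,
)


class TestBoxplotOutliers:
    def test_single_extreme_excluded(self):
        mask = boxplot_outlier_mask(np.array([1, 2, 3, 4, 100.0]))
        np.testing.assert_array_equal(mask, [True, True, True, True, False])

    def test_all_equal_all_kept(self):
        assert boxplot_outlier_mask(np.full(6, 3.3)).all()

    def test_clean_symmetric_data_all_kept(self):
        values = np.array([-2, -1, -0.5, 0, 0.5, 1, 2.0])
        assert boxplot_outlier_mask(values).all()

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            boxplot_outlier_mask(np.array([1.0, 2.0, 3.0]))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney_test(np.full(5, 2.0), np.full(5, 2.0))
        assert res.p == 1.0

    def test_complete_separation_exact_p(self):
        res = mann_whitney_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert res.u == 0.0
        assert res.w == 6.0  # ranks 1+2+3
        assert res.p == pytest.approx(0.1)

    def test_statistic_is_rank_sum(self):
        a = np.array([3.1, 7.2, 0.4, 5.5])
        b = np.array([1.0, 6.3, 2.2])
        res = mann_whitney_test(a, b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        assert res.w == pytest.approx(ranks[: len(a)].sum())
        assert res.u == pytest.approx(res.w - 4 * 5 / 2)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            a = rng.standard_normal(5)
            b = rng.standard_normal(4) + 0.5
            res = mann_whitney_test(a, b)
            u_oracle, p_oracle = oracles.mann_whitney_exact_p(a, b)
            assert res.u == pytest.approx(u_oracle)
            assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.standard_normal(25)
        b = rng.standard_normal(30) + 0.7
        res_raw = mann_whitney_test(a, b)
        res_exp = mann_whitney_test(np.exp(a), np.exp(b))
        assert res_raw.u == res_exp.u
        assert res_raw.p == pytest.approx(res_exp.p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test(np.array([]), np.array([1.0]))


class TestFDR:
    def test_hand_computed_vector(self):
        np.testing.assert_allclose(
            bh_fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr_adjust(np.array([0.3])), [0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_step_up_oracle_and_inflates(self, pvals):
        p = np.array(pvals)
        adjusted = bh_fdr_adjust(p)
        np.testing.assert_allclose(adjusted, oracles.bh_adjust(p), atol=1e-12)
        assert np.all(adjusted >= p - 1e-15)
        assert np.all(adjusted <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    def test_permuting_family_permutes_output(self, rng):
        p = rng.random(12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_fdr_adjust(p)[perm], bh_fdr_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr_adjust(np.array([0.5, 1.2]))


class TestCliffsDelta:
    def test_complete_separation(self):
        delta, lo, hi = cliffs_delta(np.array([4.0, 5, 6]), np.array([1.0, 2, 3]))
        assert delta == 1.0 and hi == 1.0

    def test_identical_groups(self):
        delta, lo, hi = cliffs_delta(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert delta == 0.0
        assert lo <= 0.0 <= hi

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            delta, lo, hi = cliffs_delta(a, b)
            assert delta == pytest.approx(oracles.cliffs_delta_pairs(a, b), abs=1e-12)
            # dominance-probability identity: delta = 2 P(a>b) + P(a=b) - 1
            gt = np.mean([x > y for x in a for y in b])
            eq = np.mean([x == y for x in a for y in b])
            assert delta == pytest.approx(2 * gt + eq - 1, abs=1e-12)
            assert -1.0 <= lo <= delta <= hi <= 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12)
        assert cliffs_delta(a, b)[0] == pytest.approx(-cliffs_delta(b, a)[0])

    def test_ci_shrinks_with_sample_size(self, rng):
        a_small = rng.standard_normal(10) + 0.5
        b_small = rng.standard_normal(10)
        a_big = rng.standard_normal(400) + 0.5
        b_big = rng.standard_normal(400)
        _, lo_s, hi_s = cliffs_delta(a_small, b_small)
        _, lo_b, hi_b = cliffs_delta(a_big, b_big)
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            cliffs_delta(np.array([1.0]), np.array([1.0, 2.0]))


class TestAncova:
    def test_matches_textbook_sums_of_squares(self):
        y = np.array([10.0, 11.0, 12.5, 8.0, 9.2, 10.1])
        group = np.array(["A", "A", "A", "B", "B", "B"])
        age = np.array([30.0, 40.0, 55.0, 28.0, 42.0, 50.0])
        f, p, adjusted = ancova_group_age(y, group, age)
        f_oracle, p_oracle = oracles.ancova_f_textbook(y, group, age)
        assert f == pytest.approx(f_oracle, rel=1e-10)
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert set(adjusted) == {"A", "B"}

    def test_strong_group_shift_detected(self, rng):
        age = np.concatenate([rng.uniform(20, 60, 20), rng.uniform(20, 60, 20)])
        group = np.array(["HC"] * 20 + ["SM"] * 20)
        y = np.where(group == "SM", 5.0, 0.0) + 0.5 * rng.standard_normal(40)
        f, p, adjusted = ancova_group_age(y, group, age)
        assert p < 1e-6
        assert adjusted["SM"] - adjusted["HC"] == pytest.approx(5.0, abs=0.5)

    def test_constant_response_degenerates_to_null(self):
        f, p, _ = ancova_group_age(
            np.full(8, 2.0), np.array(["A"] * 4 + ["B"] * 4), np.arange(8.0)
        )
        assert (f, p) == (0.0, 1.0)

    def test_collinearity_and_size_checks(self):
        group = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError, match="collinear|vary"):
            ancova_group_age(np.arange(8.0), group, np.full(8, 40.0))
        with pytest.raises(ValueError, match="3 subjects"):
            ancova_group_age(np.arange(5.0), np.array(["A", "A", "B", "B", "B"]), np.arange(5.0))

    def test_null_permutation_rejection_rate(self, rng):
        y = rng.standard_normal(30)
        age = rng.uniform(20, 60, 30)
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            group = rng.permutation(np.array(["A"] * 15 + ["B"] * 15))
            _, p, _ = ancova_group_age(y, group, age)
            rejections += p < 0.05
        band = stats.binom.interval(0.95, n_perm, 0.05)
        assert band[0] <= rejections <= band[1]


class TestTiedrank:
    def test_tie_spans_averaged(self):
        np.testing.assert_allclose(tiedrank(np.array([10, 20, 20, 30.0])), [1, 2.5, 2.5, 4])

    def test_strictly_increasing(self):
        np.testing.assert_allclose(tiedrank(np.arange(5.0)), [1, 2, 3, 4, 5])

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_sum_conserved(self, values):
        n = len(values)
        assert tiedrank(np.array(values)).sum() == pytest.approx(n * (n + 1) / 2)


class TestPartialSpearman:
    def test_reduces_to_spearman_without_covariates(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        result = partial_spearman(x, y)
        rho, p = stats.spearmanr(x, y)
        assert result.rho == pytest.approx(rho, abs=1e-12)
        assert result.p == pytest.approx(p, abs=1e-10)

    def test_monotone_relationship_approaches_one(self, rng):
        x = rng.standard_normal(500)
        covs = rng.standard_normal((500, 2))
        result = partial_spearman(x, np.exp(x), covs)
        assert result.rho > 0.95

    def test_shared_confounder_removed(self, rng):
        rhos = []
        for _ in range(40):
            confounder = rng.standard_normal(80)
            x = confounder + 0.3 * rng.standard_normal(80)
            y = confounder + 0.3 * rng.standard_normal(80)
            rhos.append(partial_spearman(x, y, confounder).rho)
        assert abs(np.mean(rhos)) < 0.1
        assert partial_spearman(x, y).rho > 0.7  # raw correlation was strong

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(60)
        z = rng.standard_normal((60, 2))
        y = 0.4 * x + 0.5 * z[:, 0] + rng.standard_normal(60)
        result = partial_spearman(x, y, z)
        frame = pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1]})
        ref = pingouin.partial_corr(
            frame, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )
        assert result.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert result.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), rng.standard_normal(10))
        with pytest.raises(ValueError, match="observations"):
            partial_spearman(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestCompareGroupsTable:
    @staticmethod
    def _frame(rng, n=40, shift=0.0):
        idx = pd.Index([f"s{i}" for i in range(2 * n)], name="subject_id")
        groups = pd.Series(["HC"] * n + ["SM"] * n, index=idx)
        values = pd.DataFrame(
            {"v1": rng.standard_normal(2 * n), "v2": rng.standard_normal(2 * n)},
            index=idx,
        )
        values.loc[groups == "SM", "v1"] -= shift
        return values, groups

    def test_shifted_variable_detected_with_positive_delta(self, rng):
        values, groups = self._frame(rng, shift=1.5)
        results = compare_groups_table(values, groups, family="demo")
        by_name = {r.variable: r for r in results}
        assert by_name["v1"].delta > 0.5  # HC stochastically larger
        assert by_name["v1"].p_adj < 0.01
        assert by_name["v1"].median_a > by_name["v1"].median_b
        assert by_name["v2"].p_adj >= by_name["v2"].p

    def test_outlier_removed_and_result_stable(self, rng):
        # uniform draws produce no natural boxplot outliers, so exactly the
        # injected wild value is screened out
        idx = pd.Index([f"s{i}" for i in range(80)], name="subject_id")
        groups = pd.Series(["HC"] * 40 + ["SM"] * 40, index=idx)
        values = pd.DataFrame({"v1": rng.uniform(0, 1, 80)}, index=idx)
        values.loc[groups == "SM", "v1"] -= 0.3
        clean = compare_groups_table(values, groups, remove_outliers=True)
        assert clean[0].n_a == 40 and clean[0].n_b == 40
        spoiled = values.copy()
        spoiled.iloc[0, 0] = 1e4  # wild HC value
        trimmed = compare_groups_table(spoiled, groups, remove_outliers=True)
        assert trimmed[0].n_a == 39
        reference = compare_groups_table(
            values.iloc[1:], groups.iloc[1:], remove_outliers=True
        )
        assert trimmed[0].u == pytest.approx(reference[0].u, abs=1e-9)
        assert trimmed[0].p == pytest.approx(reference[0].p, abs=1e-12)
        # and without trimming the wild value shifts the statistic
        untrimmed = compare_groups_table(spoiled, groups)
        assert untrimmed[0].u != clean[0].u

    def test_alignment_required(self, rng):
        values, groups = self._frame(rng)
        with pytest.raises(ValueError, match="aligned"):
            compare_groups_table(values.iloc[::-1], groups)
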