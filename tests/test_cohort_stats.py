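"""Contingency tests, ANOVA+LSD, rank-sum, survival, propensity matching."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from immunodissect.cohort_stats import (
    anova_lsd,
    chi_square_test,
    fisher_exact,
    kaplan_meier,
    logrank_test,
    propensity_match,
    wilcoxon_rank_sum,
)


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        chi2, df, p = chi_square_test([[10, 20], [10, 20]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_matches_direct_formula(self):
        table = np.array([[30, 10], [20, 40]])
        chi2, df, p = chi_square_test(table)
        # independent direct evaluation of sum (O-E)^2/E
        total = table.sum()
        E = np.outer(table.sum(1), table.sum(0)) / total
        expected_chi2 = ((table - E) ** 2 / E).sum()
        assert chi2 == pytest.approx(expected_chi2)
        assert p == pytest.approx(sps.chi2.sf(expected_chi2, df))

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_test([[1, 2]])


class TestFisher:
    def test_diagonal_table_exact_enumeration(self):
        # P(both margins 5/5 split perfectly): 2 / C(10,5) = 2/252
        _, p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_flat_table_p_one(self):
        _, p = fisher_exact([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_agreement_with_chi_square_on_large_table(self):
        table = [[120, 100], [90, 110]]
        _, p_f = fisher_exact(table)
        _, _, p_c = chi_square_test(table)
        assert abs(p_f - p_c) < 0.02

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestAnovaLsd:
    def test_equal_means_near_zero_f(self, rng):
        idx = [f"s{i}" for i in range(60)]
        vals = pd.Series(rng.normal(5, 1, 60), index=idx)
        groups = pd.Series(["a", "b", "c"] * 20, index=idx)
        res = anova_lsd(vals, groups)
        assert res.p_value > 0.05

    def test_lsd_equals_pooled_t_for_two_groups(self, rng):
        idx = [f"s{i}" for i in range(30)]
        vals = pd.Series(rng.normal(0, 1, 30), index=idx)
        vals.iloc[:15] += 0.8
        groups = pd.Series(["x"] * 15 + ["y"] * 15, index=idx)
        res = anova_lsd(vals, groups)
        t_ref, p_ref = sps.ttest_ind(
            vals[groups == "x"], vals[groups == "y"], equal_var=True
        )
        row = res.pairwise.iloc[0]
        assert row["t"] == pytest.approx(t_ref)
        assert row["p_value"] == pytest.approx(p_ref)

    def test_planted_offsets_detected(self, rng):
        hits = 0
        for rep in range(40):
            r = np.random.default_rng(1000 + rep)
            idx = [f"s{i}" for i in range(90)]
            vals = pd.Series(r.normal(0, 1, 90), index=idx)
            groups = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30, index=idx)
            vals[groups == "b"] += 1.0
            vals[groups == "c"] += 2.0
            if anova_lsd(vals, groups).p_value < 0.01:
                hits += 1
        assert hits / 40 >= 0.95


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_full_enumeration(self):
        x, y = [1, 2, 3], [4, 5, 6]
        _, p = wilcoxon_rank_sum(x, y)
        # full permutation enumeration oracle for the rank-sum distribution
        pooled = x + y
        obs = sum(sorted(pooled).index(v) + 1 for v in x)  # rank sum of x = 6
        count_le = 0
        total = 0
        for combo in itertools.combinations(range(1, 7), 3):
            total += 1
            if sum(combo) <= obs:
                count_le += 1
        exact_one_tail = count_le / total  # = 1/20
        assert exact_one_tail == pytest.approx(1 / 20)
        assert p == pytest.approx(2 * exact_one_tail)

    def test_exact_and_approximate_agree_at_boundary(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 6)
        _, p_exact = wilcoxon_rank_sum(x, y)  # n=12 -> exact
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        assert abs(p_exact - res.pvalue) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        idx = list("abcd")
        res = kaplan_meier(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=idx),
            pd.Series([1, 1, 1, 1], index=idx),
        )
        curve = res.curves["all"].set_index("time")["survival"]
        np.testing.assert_allclose(
            curve.loc[[1.0, 2.0, 3.0, 4.0]], [0.75, 0.5, 0.25, 0.0]
        )

    def test_all_censored_flat_at_one(self):
        idx = list("abc")
        res = kaplan_meier(
            pd.Series([5.0, 6.0, 7.0], index=idx),
            pd.Series([0, 0, 0], index=idx),
        )
        assert (res.curves["all"]["survival"] == 1.0).all()
        assert math.isnan(res.medians["all"])

    def test_duplicated_dataset_same_curve(self, rng):
        t = rng.exponential(10, 30)
        e = (rng.random(30) < 0.7).astype(int)
        idx1 = [f"a{i}" for i in range(30)]
        idx2 = [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)]
        r1 = kaplan_meier(pd.Series(t, index=idx1), pd.Series(e, index=idx1))
        r2 = kaplan_meier(
            pd.Series(np.tile(t, 2), index=idx2),
            pd.Series(np.tile(e, 2), index=idx2),
        )
        np.testing.assert_allclose(
            r1.curves["all"]["survival"], r2.curves["all"]["survival"]
        )


class TestLogrank:
    def test_identical_groups_p_one(self):
        idx = [f"s{i}" for i in range(8)]
        t = pd.Series([1, 2, 3, 4, 1, 2, 3, 4.0], index=idx)
        e = pd.Series([1] * 8, index=idx)
        g = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
        chi2, df, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_matches_hand_computed_oe(self):
        # A events at 1,2; B events at 3,4; no censoring.
        idx = list("abcd")
        t = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        e = pd.Series([1, 1, 1, 1], index=idx)
        g = pd.Series(["A", "A", "B", "B"], index=idx)
        chi2, df, p = logrank_test(t, e, g)
        # hand computation: O_A=2, E_A = 2/4 + 1/3 = 5/6,
        # V = sum over event times of n1 n2 d (n-d) / (n^2 (n-1))
        # t=1: 2*2*1*3/(16*3)=1/4; t=2: 1*2*1*2/(9*2)=2/9; t=3: 0; t=4: 0
        V = 1 / 4 + 2 / 9
        expected = (2 - 5 / 6) ** 2 / V
        assert chi2 == pytest.approx(expected, rel=1e-6)
        assert df == 1

    def test_time_rescaling_invariance(self, rng):
        idx = [f"s{i}" for i in range(50)]
        t = pd.Series(rng.exponential(10, 50), index=idx)
        e = pd.Series((rng.random(50) < 0.8).astype(int), index=idx)
        g = pd.Series(rng.choice(["A", "B"], 50), index=idx)
        _, _, p1 = logrank_test(t, e, g)
        _, _, p2 = logrank_test(t * 365.25, e, g)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_power_on_hazard_ratio_two(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            r = np.random.default_rng(500 + rep)
            n = 200
            idx = [f"s{i}" for i in range(2 * n)]
            t = np.concatenate([r.exponential(10, n), r.exponential(5, n)])
            cens = r.uniform(0, 30, 2 * n)
            time = pd.Series(np.minimum(t, cens), index=idx)
            event = pd.Series((t <= cens).astype(int), index=idx)
            g = pd.Series(["A"] * n + ["B"] * n, index=idx)
            if logrank_test(time, event, g)[2] < 0.01:
                hits += 1
        assert hits / reps >= 0.9


class TestPropensityMatch:
    def _covs(self, rng, n):
        return pd.DataFrame(
            {
                "age": rng.normal(50, 10, n),
                "stage": rng.choice(["I", "II", "III", "Unknown"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_independent_treatment_matches_most(self, rng):
        n = 300
        covs = self._covs(rng, n)
        treat = pd.Series(rng.random(n) < 0.4, index=covs.index).astype(int)
        res = propensity_match(covs, treat, seed=1)
        assert res.n_matched / res.n_treated >= 0.8
        assert (res.smd_after < 0.1).all()

    def test_identical_covariates_complete_matching(self):
        n = 40
        covs = pd.DataFrame({"x": np.ones(n)}, index=[f"s{i}" for i in range(n)])
        treat = pd.Series([1] * 15 + [0] * 25, index=covs.index)
        res = propensity_match(covs, treat, seed=0)
        assert res.n_matched == 15
        assert (res.smd_after.fillna(0) == 0).all()

    def test_confounding_reduced_by_matching(self, rng):
        n = 500
        x = rng.normal(0, 1, n)
        logit = 1.5 * x
        treat = pd.Series(
            (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int),
            index=[f"s{i}" for i in range(n)],
        )
        covs = pd.DataFrame({"x": x}, index=treat.index)
        res = propensity_match(covs, treat, seed=2)
        assert res.smd_before["x"] > 0.5
        assert (res.smd_after < 0.1).all()
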