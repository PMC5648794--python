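import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import histomorph as hm
from histomorph.survival_stats import (
    cox_multivariable,
    cox_risk_scores,
    fisher_exact_2x2,
    km_curve,
    km_logrank,
    mcnemar,
    stratify,
)


class TestKaplanMeierLogrank:
    def test_no_events_gives_null_test(self):
        times = np.array([5.0, 8.0, 3.0, 9.0])
        events = np.zeros(4, dtype=bool)
        groups = np.array(["a", "a", "b", "b"])
        _, chi2, p = km_logrank(times, events, groups)
        assert chi2 == 0.0
        assert p == 1.0

    def test_identical_groups_give_zero_statistic(self):
        times = np.array([2.0, 5.0, 7.0] * 2)
        events = np.array([True, True, False] * 2)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        _, chi2, _ = km_logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_six_subject_worked_example(self):
        """Group A events at 1,2,3; B at 4,5,6; no censoring.  The chi-square
        is computed by hand from the observed-minus-expected table."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=bool)
        groups = np.array(["A", "A", "A", "B", "B", "B"])

        # hand computation: at each event time t, E_A = d * nA/n, V = d*(n-d)/... (d=1)
        o_minus_e = 0.0
        var = 0.0
        at_risk_a, at_risk_b = 3, 3
        for t, g in zip(times, groups):
            n = at_risk_a + at_risk_b
            e_a = at_risk_a / n
            o_a = 1.0 if g == "A" else 0.0
            o_minus_e += o_a - e_a
            var += (at_risk_a * at_risk_b) / (n * n)  # d=1, hypergeometric var
            if g == "A":
                at_risk_a -= 1
            else:
                at_risk_b -= 1
        expected_chi2 = o_minus_e**2 / var

        _, chi2, p = km_logrank(times, events, groups)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)
        assert p < 0.05

    def test_km_without_censoring_is_empirical_survival(self, rng):
        times = rng.exponential(10, 40).round(3)
        events = np.ones(40, dtype=bool)
        curve = km_curve(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_curve_invariants(self, rng):
        times = rng.exponential(10, 50)
        events = rng.random(50) < 0.7
        curve = km_curve(times, events)
        assert np.all(np.diff(curve.survival) <= 1e-12)  # non-increasing
        assert np.all(curve.survival >= 0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [True, True], ["a", "a"])


class TestCoxMultivariable:
    def test_hazard_ratio_recovery_within_ci(self):
        """Two-group exponential data with true HR 3, n=500: the estimate's
        own 95% CI covers the truth in >= 18/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 500)
            lam = np.where(x == 1, 3.0, 1.0)
            t = rng.exponential(1.0 / lam)
            df = pd.DataFrame({"x": x})
            res = cox_multivariable(df, t, np.ones(500, dtype=bool), {"x": 0})
            if res.loc["x", "ci_low"] <= 3.0 <= res.loc["x", "ci_high"]:
                hits += 1
        assert hits >= 18

    def test_null_covariate_coefficient_near_zero(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.integers(0, 2, 500)
            t = rng.exponential(1.0, 500)
            df = pd.DataFrame({"x": x})
            res = cox_multivariable(df, t, np.ones(500, dtype=bool), {"x": 0})
            if abs(res.loc["x", "coef"]) < 0.2:
                hits += 1
        assert hits >= 18

    def test_duplicating_subjects_preserves_estimates(self, rng):
        x = rng.integers(0, 2, 100)
        t = rng.exponential(np.where(x == 1, 0.5, 1.0))
        df = pd.DataFrame({"x": x})
        ev = np.ones(100, dtype=bool)
        a = cox_multivariable(df, t, ev, {"x": 0})
        df2 = pd.concat([df, df], ignore_index=True)
        b = cox_multivariable(df2, np.tile(t, 2), np.tile(ev, 2), {"x": 0})
        # duplication creates ties; Efron's tie correction makes the
        # invariance approximate (it is exact only under Breslow)
        assert b.loc["x", "coef"] == pytest.approx(a.loc["x", "coef"], abs=0.02)

    def test_constant_covariate_dropped(self, rng):
        df = pd.DataFrame({
            "x": rng.integers(0, 2, 100),
            "const": np.ones(100),
        })
        t = rng.exponential(1.0, 100)
        with pytest.warns(UserWarning, match="constant"):
            res = cox_multivariable(df, t, np.ones(100, dtype=bool),
                                    {"x": 0, "const": 0})
        assert "const" not in res.index


class TestRiskScores:
    def _table(self, rng, n=120):
        pheno = np.repeat([0, 1], n // 2)
        df = pd.DataFrame({
            "f1": pheno + 0.3 * rng.normal(size=n),
            "f2": -pheno + 0.3 * rng.normal(size=n),
        })
        lam = np.where(pheno == 1, 1 / 20.0, 1 / 80.0)
        t = rng.exponential(1 / lam)
        return df, t, np.ones(n, dtype=bool)

    def test_tertiles_split_120_distinct_scores_evenly(self, rng):
        df, t, ev = self._table(rng)
        rm = cox_risk_scores(df, ["f1", "f2"], t, ev)
        sizes = np.bincount(rm.groups3, minlength=3)
        assert sizes.tolist() == [40, 40, 40]
        assert np.bincount(rm.groups2, minlength=2).tolist() == [60, 60]

    def test_risk_score_is_weighted_feature_sum(self, rng):
        df, t, ev = self._table(rng)
        rm = cox_risk_scores(df, ["f1", "f2"], t, ev)
        X = df[["f1", "f2"]].to_numpy()
        expected = ((X - rm.feature_means) / rm.feature_scales) @ rm.coefs
        np.testing.assert_allclose(rm.scores, expected, atol=1e-12)
        np.testing.assert_allclose(rm.score(df), rm.scores, atol=1e-12)

    def test_constant_features_flagged_degenerate(self, rng):
        n = 30
        df = pd.DataFrame({"f1": np.ones(n), "f2": np.full(n, 3.0)})
        t = rng.exponential(10, n)
        with pytest.warns(UserWarning):
            rm = cox_risk_scores(df, ["f1", "f2"], t, np.ones(n, dtype=bool))
        assert rm.degenerate
        assert np.all(rm.coefs == 0)

    def test_three_group_logrank_significant_on_informative_features(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df, t, ev = self._table(rng)
            rm = cox_risk_scores(df, ["f1", "f2"], t, ev)
            _, _, p = km_logrank(t, ev, rm.groups3)
            if p < 0.05:
                wins += 1
        assert wins >= 16

    def test_too_few_patients_rejected(self, rng):
        df = pd.DataFrame({"f1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cox_risk_scores(df, ["f1"], [1.0, 2.0], [True, True])


def fisher_two_sided_enumeration(a, b, c, d):
    """Oracle: sum P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's."""
    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return total


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 8, 4)
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), abs=1e-12
        )

    def test_symmetric_under_row_and_column_swaps(self, rng):
        a, b, c, d = 3, 9, 6, 2
        p = fisher_exact_2x2(a, b, c, d)
        assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, abs=1e-12)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2(0, 0, 5, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestMcNemar:
    def test_identical_calls_give_one(self):
        truth = np.array([1, 0, 1, 0, 1], dtype=bool)
        calls = np.array([1, 0, 0, 0, 1], dtype=bool)
        assert mcnemar(calls, calls, truth) == 1.0

    def test_discordant_1_vs_9_binomial_sum(self):
        """b=1, c=9: p = 2*P(X<=1 | Bin(10, 1/2)) = 0.021484375."""
        n = 10
        truth = np.ones(n, dtype=bool)
        calls_a = np.ones(n, dtype=bool)
        calls_b = np.ones(n, dtype=bool)
        calls_a[0] = False      # b: a wrong where b right... (see below)
        calls_b[1:10] = False   # c: 9 pairs where a right, b wrong
        # a correct everywhere except index 0; b correct only at index 0
        p = mcnemar(calls_a, calls_b, truth)
        assert p == pytest.approx(0.021484375, abs=1e-12)

    def test_symmetric_in_the_two_classifiers(self, rng):
        truth = rng.integers(0, 2, 30).astype(bool)
        a = rng.integers(0, 2, 30).astype(bool)
        b = rng.integers(0, 2, 30).astype(bool)
        assert mcnemar(a, b, truth) == pytest.approx(mcnemar(b, a, truth), abs=1e-15)

    def test_agrees_with_statsmodels_exact(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        truth = rng.integers(0, 2, 50).astype(bool)
        a = (rng.random(50) < 0.7) == truth
        b = (rng.random(50) < 0.6) == truth
        calls_a = np.where(a, truth, ~truth)
        calls_b = np.where(b, truth, ~truth)
        ok_a = calls_a == truth
        ok_b = calls_b == truth
        table = [
            [(ok_a & ok_b).sum(), (ok_a & ~ok_b).sum()],
            [(~ok_a & ok_b).sum(), (~ok_a & ~ok_b).sum()],
        ]
        ref = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar(calls_a, calls_b, truth) == pytest.approx(ref, abs=1e-12)


class TestStratify:
    def test_cutpoint_assignment(self):
        groups = stratify(np.array([1.0, 2.0, 3.0, 4.0]), (1.5, 3.0))
        assert groups.tolist() == [0, 1, 1, 2]
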