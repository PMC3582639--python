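"""Kaplan-Meier, log-rank, Cox and association-test correctness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as ll_concordance

from cin4kit.survival_stats import (
    chi_square_association,
    concordance_index,
    cox_fit,
    cox_interaction_test,
    km_estimate,
    linear_trend,
    logrank_test,
)
from conftest import random_survival_instance
from oracles import cox_grid_oracle, logrank_oracle


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        # events at 1 and 2, censorings at 1.5 and 3:
        # S(1) = 3/4, S(2) = 3/4 * 1/2 = 3/8
        km = km_estimate([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
        assert km.times.tolist() == [1.0, 2.0]
        assert abs(km.survival[0] - 3 / 4) < 1e-12
        assert abs(km.survival[1] - 3 / 8) < 1e-12
        # Greenwood at t=1: S^2 * d/(n(n-d)) = (3/4)^2 * 1/12
        assert abs(km.greenwood_se[0] ** 2 - (3 / 4) ** 2 * (1 / 12)) < 1e-12

    def test_no_events_curve_stays_at_one(self):
        km = km_estimate([5.0, 8.0, 11.0], [0, 0, 0], truncation=10.0)
        assert km.times.size == 0
        assert km.restricted_mean == pytest.approx(10.0)

    def test_subject_duplication_leaves_curve_unchanged(self):
        t = np.array([2.0, 4.0, 5.0, 9.0])
        e = np.array([1, 0, 1, 1])
        a = km_estimate(t, e)
        b = km_estimate(np.tile(t, 2), np.tile(e, 2))
        np.testing.assert_allclose(a.survival, b.survival, atol=1e-14)
        assert a.restricted_mean == pytest.approx(b.restricted_mean)

    def test_restricted_mean_equals_mean_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(30.0, 40)
        e = np.ones(40, dtype=int)
        tau = 50.0
        km = km_estimate(t, e, truncation=tau)
        assert km.restricted_mean == pytest.approx(np.minimum(t, tau).mean(), rel=1e-10)

    def test_matches_lifelines_with_ties(self):
        rng = np.random.default_rng(11)
        _, t, e = random_survival_instance(rng, n=60, round_times=True)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[km.times, "KM_estimate"].to_numpy()
        np.testing.assert_allclose(km.survival, ref, atol=1e-12)

    def test_all_zero_times_error(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 0.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [3.0, 5.0, 7.0, 9.0]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_small_instance(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 3.0, 6.0], [1, 1, 1]
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-12)

    def test_zero_events_error(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [3.0], [0])

    def test_equals_cox_score_test_without_ties(self):
        # with untied event times the log-rank statistic is exactly the
        # partial-likelihood score test (Breslow convention) for the
        # binary group covariate
        rng = np.random.default_rng(5)
        done = 0
        while done < 50:
            x, t, e = random_survival_instance(rng, n=25, beta=0.4)
            if e.sum() < 3:
                continue
            lr = logrank_test(t[x == 1], e[x == 1], t[x == 0], e[x == 0])
            fit = cox_fit(x[:, None], t, e, ties="breslow")
            assert lr.statistic == pytest.approx(fit.score_stat, abs=1e-10)
            done += 1


class TestCox:
    def test_coefficient_matches_grid_search_oracle_small(self):
        rng = np.random.default_rng(17)
        for ties in ("efron", "breslow"):
            done = 0
            while done < 8:
                x, t, e = random_survival_instance(
                    rng, n=8, beta=0.5, round_times=True
                )
                if e.sum() < 2:
                    continue
                try:
                    fit = cox_fit(x[:, None], t, e, ties=ties)
                except Exception:
                    continue
                if abs(fit.coef[0]) > 3:  # near-separation: grid oracle unstable
                    continue
                ref = cox_grid_oracle(x, t, e, ties=ties)
                assert fit.coef[0] == pytest.approx(ref, abs=1e-4)
                done += 1

    def test_matches_lifelines_with_efron_ties(self):
        rng = np.random.default_rng(23)
        n = 80
        X = rng.normal(size=(n, 2))
        t_event = rng.exponential(60.0 * np.exp(-0.4 * X[:, 0] + 0.2 * X[:, 1]))
        c = rng.uniform(5.0, 100.0, n)
        t = np.maximum(1.0, np.round(np.minimum(t_event, c)))
        e = (t_event <= c).astype(int)
        fit = cox_fit(X, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1]}), "t", "e"
        )
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-8)
        assert fit.concordance == pytest.approx(cph.concordance_index_, abs=1e-12)

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(29)
        coefs = []
        for _ in range(30):
            x, t, e = random_survival_instance(rng, n=60, beta=0.0, binary=False)
            coefs.append(cox_fit(x[:, None], t, e).coef[0])
        assert abs(np.mean(coefs)) < 0.08

    def test_r2_definitions(self):
        rng = np.random.default_rng(31)
        x, t, e = random_survival_instance(rng, n=50, beta=0.8)
        fit = cox_fit(x[:, None], t, e)
        assert fit.r2 == pytest.approx(1 - np.exp(-fit.lr_stat / fit.n))
        assert fit.max_r2 == pytest.approx(1 - np.exp(2 * fit.loglik_null / fit.n))
        assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(np.ones((10, 1)), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_concordance_matches_lifelines(self):
        rng = np.random.default_rng(37)
        x, t, e = random_survival_instance(rng, n=70, beta=0.6, binary=False)
        risk = 0.6 * x
        assert concordance_index(t, e, risk) == pytest.approx(
            ll_concordance(t, -risk, e), abs=1e-12
        )


class TestInteraction:
    def test_collinear_design_is_flagged(self):
        rng = np.random.default_rng(41)
        a = rng.normal(size=40)
        t = rng.exponential(30.0, 40)
        e = np.ones(40, dtype=int)
        res = cox_interaction_test(a, a, t, e)
        assert "collinear_design" in res.flags
        assert np.isnan(res.p_value)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(43)
        hits = 0
        for _ in range(20):
            n = 200
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            lam = 0.01 * np.exp(0.2 * a + 0.2 * b + 0.6 * a * b)
            t_event = rng.exponential(1.0 / lam)
            c = rng.uniform(0.0, 120.0, n)
            t = np.minimum(t_event, c)
            e = (t_event <= c).astype(int)
            res = cox_interaction_test(a, b, t, e)
            hits += res.p_value < 0.05
        assert hits >= 16  # strong multiplicative effect at n=200


class TestAssociations:
    def test_chi_square_hand_checked_2x2(self):
        # 2x2 counts 44,48 / 34,50: statistic by explicit O-E arithmetic
        table = np.array([[44, 48], [34, 50]])
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / table.sum()
        by_hand = float(((table - expected) ** 2 / expected).sum())
        a = ["x"] * 92 + ["y"] * 84
        b = ["lo"] * 44 + ["hi"] * 48 + ["lo"] * 34 + ["hi"] * 50
        stat, dof, p, tab = chi_square_association(a, b)
        assert stat == pytest.approx(by_hand, abs=1e-12)
        assert dof == 1
        odds_ratio = (44 * 50) / (48 * 34)
        got = (
            tab.loc["x", "lo"] * tab.loc["y", "hi"]
            / (tab.loc["x", "hi"] * tab.loc["y", "lo"])
        )
        assert got == pytest.approx(odds_ratio)

    def test_chi_square_identical_rows_zero(self):
        a = ["u"] * 40 + ["v"] * 40
        b = (["p"] * 10 + ["q"] * 30) * 2
        stat, _, p, _ = chi_square_association(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_linear_trend_exact_line(self):
        x = np.arange(10.0)
        res = linear_trend(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_linear_trend_rejects_constant_x(self):
        with pytest.raises(ValueError):
            linear_trend(np.ones(5), np.arange(5.0))
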