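import numpy as np
import pandas as pd
import pytest

from mathsurv import cox_fit, km_estimate, logrank_test
from mathsurv.survival import _cox_loglik_grad_hess


class TestKaplanMeier:
    def test_all_censored_curve_is_flat_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(10) == 1.0

    def test_two_subject_hand_example(self):
        km = km_estimate([1, 2], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_duplicating_records_leaves_curve_unchanged(self, rng):
        t = rng.exponential(10, 30).round(2)
        e = rng.integers(0, 2, 30)
        a = km_estimate(t, e)
        b = km_estimate(np.tile(t, 2), np.tile(e, 2))
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.times, b.times)

    def test_censoring_only_shrinks_risk_set(self):
        # death at 2 with a censored 1: at-risk at t=2 excludes the censored
        km = km_estimate([1, 2, 3], [0, 1, 0])
        assert km.at_risk.tolist() == [2]
        np.testing.assert_allclose(km.survival, [0.5])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogRank:
    def test_identical_groups_give_zero(self):
        res = logrank_test([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1], list("AAABBB"))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_example_two_groups(self):
        """Deaths A:{1,2}, B:{3,4}: chi2 = (7/6)^2 / (17/36) ~ 2.88."""
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], list("AABB"))
        assert res.chi_square == pytest.approx(2.882, abs=0.01)
        assert res.p_value == pytest.approx(0.089, abs=0.002)

    def test_three_groups_df(self, rng):
        t = rng.exponential(5, 30)
        e = np.ones(30, dtype=int)
        res = logrank_test(t, e, rng.choice(list("ABC"), 30))
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["A", "A"])

    def test_invariance_relabeling_and_time_shift(self, rng):
        t = rng.exponential(5, 40).round(2)
        e = rng.integers(0, 2, 40)
        g = rng.choice(list("AB"), 40)
        base = logrank_test(t, e, g).chi_square
        relabeled = logrank_test(t, e, np.where(g == "A", "Z", "Y")).chi_square
        shifted = logrank_test(t + 7.5, e, g).chi_square
        assert relabeled == pytest.approx(base, rel=1e-12)
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(5, 60).round(2)
        e = rng.integers(0, 2, 60)
        g = rng.choice(list("ABC"), 60)
        ours = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)


def toy_binary_fixture():
    times = np.array([5, 6, 7, 8, 2, 3, 4, 9.0])
    events = np.array([1, 1, 0, 1, 1, 1, 1, 0])
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
    return times, events, x


class TestCoxFit:
    def test_grid_search_oracle(self):
        """NR solution matches a dense grid over the partial likelihood."""
        times, events, x = toy_binary_fixture()

        def pl(beta):  # no ties in this fixture
            order = np.argsort(-times)
            ll, cum = 0.0, 0.0
            for i in order:
                cum += np.exp(beta * x[i])
                if events[i]:
                    ll += beta * x[i] - np.log(cum)
            return ll

        grid = np.arange(-5, 5, 1e-4)
        beta_grid = grid[np.argmax([pl(b) for b in grid])]
        fit = cox_fit(times, events, x)
        assert fit.converged
        assert fit.table["coef"][0] == pytest.approx(beta_grid, abs=2e-4)

    def test_agrees_with_lifelines_multivariate(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        X = rng.standard_normal((n, 3))
        t = rng.exponential(np.exp(-(0.5 * X[:, 0])), n).round(3) + 0.01
        e = rng.integers(0, 2, n)
        fit = cox_fit(t, e, pd.DataFrame(X, columns=list("abc")))
        df = pd.DataFrame(X, columns=list("abc")).assign(t=t, e=e)
        ref = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.table["coef"], ref.params_.values, atol=2e-4)
        np.testing.assert_allclose(fit.table["se"], ref.standard_errors_.values, atol=2e-4)

    def test_null_covariate_near_zero(self, rng):
        n = 200
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)  # unrelated to survival
        fit = cox_fit(t, e, x)
        assert abs(fit.table["coef"][0]) < 0.15

    def test_time_scaling_invariance(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        x = rng.standard_normal(50)
        a = cox_fit(t, e, x)
        b = cox_fit(2 * t, e, x)
        assert b.table["coef"][0] == pytest.approx(a.table["coef"][0], abs=1e-8)

    def test_breslow_and_efron_agree_without_ties(self):
        times, events, x = toy_binary_fixture()
        a = cox_fit(times, events, x, tie_method="efron")
        b = cox_fit(times, events, x, tie_method="breslow")
        assert a.table["coef"][0] == pytest.approx(b.table["coef"][0], abs=1e-10)

    def test_efron_ties_agree_with_lifelines(self, rng):
        from lifelines import CoxPHFitter

        n = 80
        t = rng.integers(1, 8, n).astype(float)  # heavy ties
        e = rng.integers(0, 2, n)
        x = rng.standard_normal(n)
        fit = cox_fit(t, e, x)
        ref = CoxPHFitter().fit(pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e")
        assert fit.table["coef"][0] == pytest.approx(ref.params_["x"], abs=1e-5)

    def test_score_test_at_zero_equals_logrank(self, rng):
        """Classical equivalence for a binary covariate without ties."""
        n = 40
        t = np.sort(rng.uniform(0, 100, n))  # distinct times
        e = rng.integers(0, 2, n)
        e[:3] = 1
        x = rng.integers(0, 2, n).astype(float)
        xc = (x - x.mean())[:, None]
        order = np.argsort(-t)
        _, score, info = _cox_loglik_grad_hess(
            np.zeros(1), t[order], e[order], xc[order], "efron"
        )
        score_chi2 = score[0] ** 2 / info[0, 0]
        lr = logrank_test(t, e, x).chi_square
        assert score_chi2 == pytest.approx(lr, abs=1e-6)

    def test_separation_is_flagged(self):
        # perfect separation: all deaths in one arm, first in time order
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13.0])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0.0])
        fit = cox_fit(t, e, x)
        assert not fit.converged
        assert "monotone_likelihood" in fit.flags or "not_converged" in fit.flags

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 0, 1], np.ones(4))
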