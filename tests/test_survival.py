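import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import mirecur as mr
from mirecur.survival import cox_fit_multi, cox_fit_single, cox_univariate_many

from conftest import random_survival_instance


def efron_partial_loglik(beta_grid, x, time, event):
    """Independent Efron partial log-likelihood, evaluated on a grid of betas.

    Deliberately written as explicit loops over event groups, independent of
    the package's vectorized solver.
    """
    beta_grid = np.atleast_1d(beta_grid)
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = np.zeros(len(beta_grid))
    for g, beta in enumerate(beta_grid):
        w = np.exp(beta * x)
        total = 0.0
        for t in np.unique(time[event == 1]):
            tied = (time == t) & (event == 1)
            at_risk = time >= t
            d = tied.sum()
            s0 = w[at_risk].sum()
            s0d = w[tied].sum()
            total += beta * x[tied].sum()
            for l in range(d):
                total -= np.log(s0 - (l / d) * s0d)
        ll[g] = total
    return ll


class TestCoxFit:
    def test_matches_grid_search_oracle(self):
        """Newton solution maximizes the Efron partial likelihood (grid oracle)."""
        rng = np.random.default_rng(42)
        grid = np.arange(-5.0, 5.0001, 1e-3)
        checked = 0
        while checked < 25:
            x, t, e = random_survival_instance(rng)
            if np.ptp(x) == 0:
                continue
            fit = cox_fit_single(x, t, e)
            if not fit.converged:
                continue
            ll = efron_partial_loglik(grid, x - x.mean(), t, e)
            if ll.max() - ll.min() < 1e-8:
                continue  # flat partial likelihood: every beta is a maximizer
            best = grid[np.argmax(ll)]
            assert fit.beta == pytest.approx(best, abs=2e-3)
            checked += 1

    def test_spec_four_subject_instance(self):
        # covariate (1,0,1,0), all events at distinct times; score at 0 is +2/3
        fit = cox_fit_single([1, 0, 1, 0], [1, 2, 3, 4], [1, 1, 1, 1])
        grid = np.arange(-5.0, 5.0001, 1e-4)
        ll = efron_partial_loglik(grid, np.array([1, 0, 1, 0]) - 0.5, [1, 2, 3, 4], [1, 1, 1, 1])
        assert fit.beta > 0
        assert fit.beta == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_matches_lifelines_multivariate(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.standard_normal((n, 3))
        t = rng.exponential(1000 / np.exp(0.5 * X[:, 0] - 0.4 * X[:, 1]))
        e = (rng.uniform(size=n) < 0.7).astype(int)
        e[0] = 1
        model = cox_fit_multi(X, t, e)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(model.betas, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(model.se, ref.standard_errors_.values, atol=1e-5)

    def test_constant_covariate_degenerate(self):
        fit = cox_fit_single([2, 2, 2, 2], [1, 2, 3, 4], [1, 1, 0, 1])
        assert fit.degenerate
        assert fit.beta == 0.0
        assert fit.hazard_ratio == 1.0
        assert fit.p == 1.0

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        t = rng.uniform(1, 100, size=30)
        e = (rng.uniform(size=30) < 0.6).astype(int)
        e[0] = 1
        a, b = cox_fit_single(x, t, e), cox_fit_single(-x, t, e)
        assert a.beta == pytest.approx(-b.beta, abs=1e-9)
        assert a.p == pytest.approx(b.p, abs=1e-9)

    def test_scaling_covariate_scales_beta_not_p(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        t = rng.uniform(1, 100, size=40)
        e = np.ones(40, dtype=int)
        a, b = cox_fit_single(x, t, e), cox_fit_single(10 * x, t, e)
        assert a.beta == pytest.approx(10 * b.beta, rel=1e-6)
        assert a.p == pytest.approx(b.p, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            cox_fit_single([1, 2], [1, 2], [0, 0])

    def test_monotone_likelihood_flagged(self):
        # perfectly separated covariate drives |beta| beyond the guard
        fit = cox_fit_single([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        assert not fit.converged

    def test_vectorized_univariate_agrees_with_single(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((25, 8))
        t = rng.uniform(1, 50, size=25)
        e = (rng.uniform(size=25) < 0.7).astype(int)
        e[:2] = 1
        many = cox_univariate_many(X, t, e)
        for j in range(8):
            one = cox_fit_single(X[:, j], t, e)
            assert many["beta"][j] == pytest.approx(one.beta, abs=1e-9)
            assert many["p"][j] == pytest.approx(one.p, abs=1e-9)


class TestPredictCurve:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 2))
        t = rng.uniform(10, 1000, size=40)
        e = (rng.uniform(size=40) < 0.7).astype(int)
        e[0] = 1
        return cox_fit_multi(X, t, e)

    def test_training_means_give_baseline(self, model):
        curve = model.predict_curve(model.training_means)
        np.testing.assert_allclose(curve.survival, model.baseline_curve.survival)

    def test_zero_beta_gives_identical_curves(self):
        t = np.array([5.0, 10.0, 20.0, 40.0])
        e = np.array([1, 1, 0, 1])
        X = np.array([[2.0], [2.0], [2.0], [2.0]])  # constant -> beta 0
        model = cox_fit_multi(X, t, e)
        a = model.predict_curve([0.0])
        b = model.predict_curve([100.0])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_closed_form_power(self):
        # S = S0 ** exp(lp): with S0 = exp(-0.1) and lp = log 2, S = exp(-0.2)
        s0 = np.exp(-0.1)
        hr = np.exp(np.log(2.0))
        assert s0**hr == pytest.approx(np.exp(-0.2))

    def test_monotone_in_linear_predictor(self, model):
        lo = model.predict_curve(model.training_means - model.betas)
        hi = model.predict_curve(model.training_means + model.betas)
        # larger linear predictor => pointwise lower survival
        assert np.all(hi.survival <= lo.survival + 1e-12)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="dimension"):
            model.predict_curve([1.0, 2.0, 3.0])


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = mr.km_estimate([5, 10, 15], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_product_limit_hand_example(self):
        curve = mr.km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3) == pytest.approx(0.0)

    def test_all_events_at_one_time(self):
        curve = mr.km_estimate([7, 7, 7, 7], [1, 1, 1, 1])
        assert curve.at(7) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        curve = mr.km_estimate(t, np.ones(5, dtype=int))
        for u in [1, 2, 3, 4, 5]:
            assert curve.at(u) == pytest.approx((t > u).mean())


class TestTwoGroupTests:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3], [1, 0, 1]
        chi2, p = mr.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_hand_computation(self):
        # A events at 1,2; B events at 3,4: O-E = 7/6, V = 17/36 -> chi2 = 49/17
        chi2, p = mr.logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)

    def test_logrank_symmetric_in_labels(self):
        rng = np.random.default_rng(9)
        ta, tb = rng.uniform(1, 50, 12), rng.uniform(1, 80, 15)
        ea = (rng.uniform(size=12) < 0.7).astype(int)
        eb = (rng.uniform(size=15) < 0.7).astype(int)
        ea[0] = eb[0] = 1
        assert mr.logrank_test(ta, ea, tb, eb)[0] == pytest.approx(
            mr.logrank_test(tb, eb, ta, ea)[0], rel=1e-9
        )

    def test_gehan_hand_computation(self):
        # U = 4*(1/2) + 3*(2/3) = 4; Var = 16*(1/4) + 9*(2/9) = 6; chi2 = 16/6
        chi2, p = mr.gehan_wilcoxon_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(16 / 6, rel=1e-9)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            chi2, p = mr.logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert p == 1.0
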