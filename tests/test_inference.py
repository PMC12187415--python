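import numpy as np
import pytest

from fishsde import (
    DistanceSeries,
    SSRConfig,
    bin_average,
    build_library,
    km_point_estimates,
    lasso_cd,
    ssr_fit,
)
from fishsde.inference import (
    DegenerateModelError,
    lasso_lambda_max,
    pool_estimates,
)
from fishsde.potential import DiffusionParams, PolynomialModel, SDEModel
from fishsde.simulate import SimConfig, simulate_paths
from fishsde.stats import linear_regression


def dseries(values, dt=1 / 30):
    return DistanceSeries(x=np.asarray(values, float), dt=dt, trial_id="t")


OU = SDEModel(
    drift=PolynomialModel([12.0, -1.0, 0.0, 0.0], target="drift"),
    diffusion=DiffusionParams(b0=1.0, b1=0.0, b2=0.0),
    domain=(0.0, 57.0),
)


class TestKMPointEstimates:
    def test_linear_ramp(self):
        c, dt = 2.0, 1 / 30
        x = c * np.arange(100) * dt
        est = km_point_estimates(dseries(x, dt))
        np.testing.assert_allclose(est.drift_hat, c, atol=1e-9)
        np.testing.assert_allclose(est.diff2_hat, c**2 * dt, atol=1e-9)
        np.testing.assert_allclose(est.y, x[:-1])

    def test_constant_series(self):
        est = km_point_estimates(dseries(np.full(50, 7.0)))
        np.testing.assert_allclose(est.drift_hat, 0.0)
        np.testing.assert_allclose(est.diff2_hat, 0.0)

    def test_ou_conditional_moments(self):
        # OU with theta=1, mu=12, sigma=1: binned drift is a line with
        # slope -1 and intercept 12; mean squared increment per dt is
        # sigma^2 = 1
        paths = simulate_paths(OU, SimConfig(x0=12.0, seed=7, n_trials=10))
        pooled = pool_estimates([km_point_estimates(p) for p in paths])
        binned = bin_average(pooled, 0.1, 10)
        reg = linear_regression(binned.state, binned.mean_drift)
        assert reg.slope == pytest.approx(-1.0, abs=0.1)
        assert reg.intercept == pytest.approx(12.0, abs=1.2)
        assert pooled.diff2_hat.mean() == pytest.approx(1.0, abs=0.1)

    def test_filtering_is_optional_and_smooths(self, rng):
        x = 10 + rng.normal(0, 1, 2000)
        raw = km_point_estimates(dseries(x))
        filt = km_point_estimates(dseries(x), filter_cutoff=0.1)
        assert filt.diff2_hat.mean() < 0.1 * raw.diff2_hat.mean()

    def test_pool_requires_matching_dt(self):
        with pytest.raises(ValueError, match="dt"):
            pool_estimates([km_point_estimates(dseries([1, 2, 3], 1 / 30)),
                            km_point_estimates(dseries([1, 2, 3], 1 / 25))])


class TestBinAverage:
    def test_binning_convention(self):
        est = km_point_estimates(dseries([0.01, 0.09, 0.01]))
        b = bin_average(est, bin_width=0.1, min_count=1)
        assert len(b.bin_centres) == 1  # both states in [0, 0.1)
        assert b.counts[0] == 2

    def test_pooling_doubles_counts_keeps_means(self):
        e = km_point_estimates(dseries([5.0, 5.02, 5.04, 5.0]))
        single = bin_average(e, min_count=1)
        double = bin_average([e, e], min_count=1)
        np.testing.assert_allclose(double.counts, 2 * single.counts)
        np.testing.assert_allclose(double.mean_drift, single.mean_drift)

    def test_min_count_drops_sparse_bins(self):
        x = np.concatenate([np.full(50, 5.01), [9.0]])
        b = bin_average(km_point_estimates(dseries(x)), min_count=10)
        assert len(b.bin_centres) == 1

    def test_empty_input(self):
        est = km_point_estimates(dseries([1.0, 1.0]))
        est.y = est.y[:0]
        est.drift_hat = est.drift_hat[:0]
        est.diff2_hat = est.diff2_hat[:0]
        assert len(bin_average(est).bin_centres) == 0


class TestBuildLibrary:
    def test_powers_row(self):
        np.testing.assert_allclose(build_library(np.array([2.0]), 3),
                                   [[1.0, 2.0, 4.0, 8.0]])

    def test_intercept_only(self):
        np.testing.assert_allclose(build_library(np.array([3.0, 4.0]), 0),
                                   [[1.0], [1.0]])

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            build_library(np.array([1.0]), -1)


class TestLassoCD:
    def test_lambda_zero_is_least_squares(self, rng):
        theta = build_library(rng.uniform(-1, 1, 200), 3)
        y = rng.normal(size=200)
        ols, *_ = np.linalg.lstsq(theta, y, rcond=None)
        np.testing.assert_allclose(lasso_cd(theta, y, 0.0), ols, atol=1e-8)

    def test_kkt_zero_threshold(self, rng):
        theta = build_library(rng.uniform(-1, 1, 300), 3)
        y = rng.normal(size=300) + theta[:, 1]
        lam_max = lasso_lambda_max(theta, y)
        at = lasso_cd(theta, y, lam_max * 1.001)
        assert np.allclose(at[1:], 0.0, atol=1e-9)
        below = lasso_cd(theta, y, lam_max * 0.9)
        assert np.abs(below[1:]).max() > 1e-6

    def test_noiseless_cubic_recovered(self, rng):
        z = rng.uniform(-1, 1, 500)
        theta = build_library(z, 3)
        truth = np.array([0.5, -1.0, 0.3, 2.0])
        y = theta @ truth
        coefs = lasso_cd(theta, y, 1e-6)
        np.testing.assert_allclose(coefs, truth, atol=1e-3)

    def test_matches_sklearn_on_standardized_design(self, rng):
        from sklearn.linear_model import Lasso

        n = 400
        x = rng.normal(size=(n, 4))
        x = (x - x.mean(0)) / x.std(0)
        y = x @ np.array([1.0, -0.5, 0.0, 0.2]) + rng.normal(0, 0.3, n)
        yc = y - y.mean()
        lam = 5.0
        ours = lasso_cd(x, yc, lam)
        ref = Lasso(alpha=lam / (2 * n), fit_intercept=False).fit(x, yc)
        np.testing.assert_allclose(ours, ref.coef_, atol=1e-4)

    def test_weighted_fit_equals_replicated_rows(self, rng):
        x = build_library(rng.uniform(-1, 1, 60), 2)
        y = x @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, 60)
        w = np.ones(60)
        w[:10] = 3.0
        xrep = np.vstack([x, x[:10], x[:10]])
        yrep = np.concatenate([y, y[:10], y[:10]])
        lam = 0.5 * len(yrep) / len(y)  # same penalty-to-loss balance
        a = lasso_cd(x, y, 0.5, weights=w)
        b = lasso_cd(xrep, yrep, lam)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            lasso_cd(np.ones((3, 1)), np.ones(3), -1.0)


class TestSSRFit:
    def test_recovers_sparse_cubic_from_noisy_data(self, rng):
        y_state = rng.uniform(2, 20, 5000)
        truth = np.array([50.0, -16.5, 1.5, -0.04])
        resp = np.polynomial.polynomial.polyval(y_state, truth) + rng.normal(
            0, 1.0, 5000
        )
        est = km_point_estimates(dseries(np.full(2, 1.0)))
        est.y, est.drift_hat = y_state, resp
        est.diff2_hat = np.ones_like(resp)
        res = ssr_fit(est, "drift", SSRConfig(seed=0, shuffle_folds=True))
        assert res.model.degree == 3
        np.testing.assert_allclose(res.model.coefficients[:4], truth, rtol=0.1)
        assert res.cv_error == pytest.approx(1.0, rel=0.2)  # noise variance

    def test_never_more_terms_than_library(self, rng):
        y_state = rng.uniform(0, 10, 1000)
        resp = 2.0 + 0.5 * y_state + rng.normal(0, 0.2, 1000)
        est = km_point_estimates(dseries(np.full(2, 1.0)))
        est.y, est.drift_hat = y_state, resp
        est.diff2_hat = np.ones_like(resp)
        cfg = SSRConfig(max_degree=4, seed=1, shuffle_folds=True)
        res = ssr_fit(est, "drift", cfg)
        assert np.count_nonzero(res.model.coefficients) <= cfg.max_degree + 1
        assert res.model.degree <= 1

    def test_diffusion_fit_is_parabolic_with_negative_curvature(self):
        # wide stationary support (theta=0.5) and pronounced curvature so
        # the parabola is identifiable from the sampled state range
        model = SDEModel(
            drift=PolynomialModel([6.0, -0.5, 0, 0], "drift"),
            diffusion=DiffusionParams(b0=-1.78, b1=0.48, b2=-0.02),
        )
        paths = simulate_paths(model, SimConfig(x0=12.0, seed=5, n_trials=6))
        pooled = pool_estimates([km_point_estimates(p) for p in paths])
        res = ssr_fit(pooled, "diffusion", SSRConfig(seed=0))
        assert res.model.degree == 2
        assert res.model.coefficients[2] < 0

    def test_history_recorded(self, rng):
        y_state = rng.uniform(0, 5, 500)
        resp = 1.0 + y_state + rng.normal(0, 0.1, 500)
        est = km_point_estimates(dseries(np.full(2, 1.0)))
        est.y, est.drift_hat = y_state, resp
        est.diff2_hat = np.ones_like(resp)
        res = ssr_fit(est, "drift", SSRConfig(seed=0))
        assert len(res.history) >= 1
        assert all(d >= 0 for _, d in res.history)

    def test_unknown_target_rejected(self):
        est = km_point_estimates(dseries(np.arange(10.0)))
        with pytest.raises(ValueError):
            ssr_fit(est, "jerk")
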