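"""Scalar Kalman filter on onset series and the execution-noise fit."""

import numpy as np
import pytest

from tempocorr import (
    KalmanGainEstimator,
    estimate_process_variance,
    fit_measurement_noise,
    kalman_filter,
    static_gain,
    steady_state_gain,
)
from tempocorr.simulate import SimulationConfig, simulate_series

from conftest import MEAN_VT


class TestGains:
    def test_symmetric_noise_gives_half(self):
        assert static_gain(0.01, 0.01) == 0.5

    def test_no_measurement_noise_gives_one(self):
        assert static_gain(0.0042, 0.0) == 1.0
        assert steady_state_gain(0.0042, 0.0) == 1.0

    def test_printed_line_label_value(self):
        # the 100-ms execution-noise line label: 0.0042/(0.0042+0.01)
        assert static_gain(0.0042, 0.01) == pytest.approx(0.29577, abs=1e-5)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            static_gain(0.0, 0.0)
        with pytest.raises(ValueError):
            steady_state_gain(0.0, 0.0)

    def test_steady_gain_solves_riccati(self):
        for vt, s2 in [(0.0042, 0.0025), (0.0042, 0.04), (0.01, 0.0001)]:
            k = steady_state_gain(vt, s2)
            assert k ** 2 * s2 == pytest.approx(vt * (1 - k), abs=1e-12)
            assert 0 < k <= 1


class TestProcessVariance:
    def test_constant_series_zero(self):
        assert estimate_process_variance(np.full(20, 0.4)).max() == 0.0

    def test_alternating_series_hand_value(self):
        # window of two 0s and two 0.1s, n-1 normalization: 0.1^2/3
        x = np.tile([0.0, 0.1], 10)
        vt = estimate_process_variance(x, window=4)
        np.testing.assert_allclose(vt, 0.01 / 3, atol=1e-15)

    def test_white_noise_mean_matches_variance(self):
        rng = np.random.default_rng(0)
        means = [
            estimate_process_variance(rng.normal(0, 0.05, 360)).mean()
            for _ in range(200)
        ]
        assert np.mean(means) == pytest.approx(0.05 ** 2, rel=0.03)

    def test_trailing_alignment_excludes_current_trial(self):
        x = np.r_[np.zeros(6), 100.0]
        vt = estimate_process_variance(x, window=4)
        # the estimate for the last trial uses trials 2..5 only
        assert vt[-1] == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_process_variance(np.array([1.0, 2.0]), window=4)


class TestKalmanFilter:
    def test_three_step_hand_recursion(self):
        # frozen values from exact rational arithmetic on the recursion
        # with obs {0.50, 0.56, 0.47}, tau0=0.50, P0=Vt=0.0042, s2=0.0025
        tr = kalman_filter(
            np.array([0.50, 0.56, 0.47]), 0.0025, 0.0042, tau0=0.50, P0=0.0042
        )
        np.testing.assert_allclose(
            tr.tau_prior, [0.5, 0.5, 0.541855930673407], atol=1e-12)
        np.testing.assert_allclose(
            tr.P_prior, [0.0042, 0.005767164179104, 0.005943997111392],
            atol=1e-12)
        np.testing.assert_allclose(
            tr.gain,
            [0.626865671641791, 0.697598844556779, 0.703931684601454],
            atol=1e-12)
        np.testing.assert_allclose(
            tr.tau_post, [0.5, 0.541855930673407, 0.491274264345870],
            atol=1e-12)
        np.testing.assert_allclose(
            tr.P_post,
            [0.001567164179104, 0.001743997111392, 0.001759829211504],
            atol=1e-12)
        np.testing.assert_allclose(
            tr.prediction_error, [0.0, 0.06, -0.071855930673407], atol=1e-12)

    def test_no_measurement_noise_tracks_observations(self):
        y = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        tr = kalman_filter(y, 0.0, 0.004, tau0=0.1, P0=0.004)
        np.testing.assert_allclose(tr.gain, 1.0)
        np.testing.assert_allclose(tr.tau_post, y)
        np.testing.assert_allclose(tr.prediction_error[1:], np.diff(y))

    def test_no_process_noise_freezes_prior(self):
        y = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        tr = kalman_filter(y, 0.0025, 0.0, tau0=0.3, P0=0.0)
        np.testing.assert_allclose(tr.gain, 0.0)
        np.testing.assert_allclose(tr.tau_post, 0.3)

    def test_matches_independent_textbook_filter(self):
        # oracle: separately coded predict/update scalar Kalman filter
        rng = np.random.default_rng(3)
        y = rng.normal(0.4, 0.1, 50)
        vt = rng.uniform(0.001, 0.01, 50)
        s2 = 0.0036
        tau, P = y[0], 0.005
        taus, gains = [], []
        for i in range(50):
            if i > 0:
                P = P + vt[i]          # predict
            K = P / (P + s2)           # update
            tau = tau + K * (y[i] - tau)
            P = (1 - K) * P
            taus.append(tau)
            gains.append(K)
        tr = kalman_filter(y, s2, vt, tau0=y[0], P0=0.005)
        np.testing.assert_allclose(tr.tau_post, taus, atol=1e-12)
        np.testing.assert_allclose(tr.gain, gains, atol=1e-12)

    def test_gain_bounded_and_posterior_never_exceeds_prior(self, rng):
        y = rng.normal(0.4, 0.1, 360)
        tr = kalman_filter(y, 0.0025, estimate_process_variance(y))
        assert ((tr.gain >= 0) & (tr.gain <= 1)).all()
        assert (tr.P_post <= tr.P_prior + 1e-18).all()

    def test_constant_noise_converges_to_riccati_root(self):
        y = np.zeros(500)
        vt, s2 = 0.0042, 0.0025
        tr = kalman_filter(y, s2, vt, tau0=0.0, P0=1.0)
        assert tr.gain[-1] == pytest.approx(steady_state_gain(vt, s2), abs=1e-10)

    def test_negative_variances_rejected(self):
        with pytest.raises(ValueError):
            kalman_filter(np.zeros(5), -0.1, 0.001)


class TestMeasurementNoiseFit:
    def test_random_walk_fits_near_lower_bound(self):
        # a pure random walk has no observation noise to absorb
        rng = np.random.default_rng(4)
        fitted = [
            fit_measurement_noise(np.cumsum(rng.normal(0, 0.065, 360))).sigma_m
            for _ in range(10)
        ]
        assert np.median(fitted) < 0.01

    def test_recovery_of_execution_noise_at_moderate_level(self):
        # series corrected at the one-step gain with sigma_m = 0.1 s
        rng = np.random.default_rng(5)
        beta = static_gain(MEAN_VT, 0.1 ** 2)
        fitted = []
        for _ in range(30):
            s = simulate_series(
                SimulationConfig(beta=beta, sigma_m=0.1), rng=rng)
            fitted.append(fit_measurement_noise(s.onset).sigma_m)
        assert np.median(fitted) == pytest.approx(0.1, rel=0.3)

    def test_sklearn_estimator_contract(self):
        est = KalmanGainEstimator(window=4)
        assert est.get_params()["window"] == 4
        est.set_params(window=5)
        y = np.cumsum(np.random.default_rng(6).normal(0, 0.05, 120))
        est.fit(y)
        for attr in ("sigma_m_", "mean_gain_", "steady_gain_", "sse_", "trace_"):
            assert hasattr(est, attr)
        assert est.predict(y).shape == y.shape
        assert 0 <= est.mean_gain_ <= 1

    def test_known_process_variance_orders_gains_by_noise(self):
        # when the generative process variance is supplied, fitted mean
        # gains decrease as the true execution noise grows
        rng = np.random.default_rng(7)
        gains = []
        for sm in (0.022, 0.05, 0.1, 0.2):
            beta = static_gain(MEAN_VT, sm ** 2)
            g = []
            for _ in range(15):
                s = simulate_series(
                    SimulationConfig(beta=beta, sigma_m=sm), rng=rng)
                g.append(
                    fit_measurement_noise(s.onset, vt=MEAN_VT).mean_gain)
            gains.append(np.mean(g))
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_literal_sse_objective_is_degenerate_on_stationary_series(self):
        # the raw prediction-error SSE prefers the running-mean predictor,
        # driving sigma_m to the upper bound on a corrected series
        rng = np.random.default_rng(8)
        s = simulate_series(SimulationConfig(beta=0.6, sigma_m=0.05), rng=rng)
        res = fit_measurement_noise(s.onset, objective="sse")
        assert res.sigma_m > 0.9

    def test_prediction_error_tracks_final_error_without_online_noise(self):
        # constant movement time, small execution noise: the filter's
        # prediction error and the (sign-flipped) final error correlate
        # strongly
        rng = np.random.default_rng(9)
        s = simulate_series(
            SimulationConfig(beta=0.7, sigma_m=0.02, sigma_x=0.0,
                             sigma_t=0.01, n_trials=360), rng=rng)
        res = fit_measurement_noise(s.onset)
        r = np.corrcoef(res.trace.prediction_error[20:], -s.error[20:])[0, 1]
        assert r > 0.8

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_measurement_noise(np.arange(5, dtype=float))
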