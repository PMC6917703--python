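"""Lag-1 dependency regression, slope->beta calibration, the coupled
time-course model, and error coupling."""

import numpy as np
import pandas as pd
import pytest

from tempocorr import (
    CoupledTimecourseModel,
    error_coupling_slope,
    fit_coupled_timecourse,
    lag1_dependency,
    slope_to_beta_calibration,
)
from tempocorr.models import _beta_t, _k_t
from tempocorr.simulate import SimulationConfig, simulate_series


def _multi_subject_table(beta, n_subjects=10, n_trials=360, sigma_m=0.05,
                         sigma_mt=0.05, seed=0):
    """Drift-free corrected series with movement-time variability."""
    root = np.random.SeedSequence(seed)
    frames = []
    for subj, child in enumerate(root.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        mt = rng.normal(0.45, sigma_mt, n_trials)
        cfg = SimulationConfig(
            beta=beta, sigma_m=sigma_m, sigma_x=0.0, sigma_t=0.0,
            n_trials=n_trials, target_time=0.8, movement_time=mt,
        )
        df = simulate_series(cfg, rng=rng).to_frame()
        df.insert(0, "subject", subj)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestLag1Dependency:
    def test_raw_slope_is_half_beta_in_drift_free_regime(self):
        # closed form: with no planning drift the population regression
        # slope of onset on the previous error is exactly beta/2,
        # independent of how the noise splits between execution and
        # movement time
        for beta in (0.2, 0.8):
            fit = lag1_dependency(_multi_subject_table(beta, seed=1),
                                  use_peaks=False)
            assert fit.slope == pytest.approx(beta / 2, abs=3 * fit.se)

    def test_zero_beta_slope_ci_covers_zero(self):
        fit = lag1_dependency(_multi_subject_table(0.0, seed=2),
                              use_peaks=False)
        assert abs(fit.slope) < 1.96 * fit.se

    def test_calibrated_recovery_of_generative_beta(self):
        icpt, coef, table = slope_to_beta_calibration(
            beta_grid=(0.0, 0.3, 0.6, 0.9), n_subjects=8, seed=3)
        for beta in (0.2, 0.5):
            fit = lag1_dependency(_multi_subject_table(beta, seed=4),
                                  use_peaks=False)
            recovered = icpt + coef * fit.slope
            assert recovered == pytest.approx(beta, abs=0.08)

    def test_calibration_monotone_through_origin(self):
        icpt, coef, table = slope_to_beta_calibration(
            beta_grid=(0.0, 0.2, 0.4, 0.6, 0.8), n_subjects=8, seed=5)
        slopes = table.sort_values("beta")["slope"].to_numpy()
        assert (np.diff(slopes) > 0).all()
        assert abs(table.loc[table["beta"] == 0.0, "slope"].iloc[0]) < 0.02
        assert coef > 0

    def test_per_subject_table_and_stratification(self):
        fit = lag1_dependency(_multi_subject_table(0.4, n_subjects=5, seed=6),
                              use_peaks=False)
        assert len(fit.per_subject) == 5
        assert np.isfinite(fit.slope_fast) and np.isfinite(fit.slope_slow)

    def test_session_boundaries_dropped(self):
        df = _multi_subject_table(0.4, n_subjects=2, seed=7)
        df["session"] = np.where(df["trial"] < 180, 1, 2)
        fit = lag1_dependency(df, use_peaks=False)
        assert fit.n_dropped_pairs == 2

    def test_too_few_trials_rejected(self):
        df = _multi_subject_table(0.4, n_subjects=1, n_trials=20, seed=8)
        with pytest.raises(ValueError, match="trials"):
            lag1_dependency(df)


class TestCoupledTimecourse:
    TRUE = dict(delta_sm=0.277, c=0.53, a=4.45)

    @staticmethod
    def _points(delta_sm, c, a, noise_sd=0.0, rng=None, t_ref=0.55):
        tm = np.linspace(0.30, 0.58, 15)
        K = _k_t(tm, delta_sm, a, c, t_ref)
        B = _beta_t(tm, delta_sm, c, t_ref)
        w = np.r_[K, B]
        if noise_sd > 0:
            w = w + rng.normal(0, noise_sd, w.size)
        return pd.DataFrame({
            "movement_time": np.r_[tm, tm],
            "kind": ["K"] * 15 + ["beta"] * 15,
            "weight": w,
        })

    def test_noiseless_recovery_to_three_decimals(self):
        fit = fit_coupled_timecourse(self._points(**self.TRUE))
        assert fit.delta_sm == pytest.approx(0.277, abs=5e-4)
        assert fit.c == pytest.approx(0.53, abs=5e-4)
        assert fit.a == pytest.approx(4.45, abs=5e-3)
        assert fit.sse < 1e-10 and fit.r2 > 0.9999

    @pytest.mark.parametrize(
        "params", [dict(delta_sm=0.2, c=0.4, a=2.0),
                   dict(delta_sm=0.35, c=0.6, a=1.0)]
    )
    def test_exact_on_self_generated_admissible_parameters(self, params):
        fit = fit_coupled_timecourse(self._points(**params))
        assert fit.sse < 1e-10
        assert fit.delta_sm == pytest.approx(params["delta_sm"], abs=1e-3)

    def test_implied_line_satisfies_constraints(self):
        fit = fit_coupled_timecourse(self._points(**self.TRUE))
        assert fit.b1 * fit.delta_sm + fit.b0 == pytest.approx(0.0, abs=1e-12)
        assert fit.b1 * 0.550 + fit.b0 == pytest.approx((1 - fit.c) ** 2,
                                                        abs=1e-6)

    def test_all_points_before_delay_give_flat_gain(self):
        tm = np.linspace(0.10, 0.24, 8)
        pts = pd.DataFrame({
            "movement_time": np.r_[tm, tm],
            "kind": ["K"] * 8 + ["beta"] * 8,
            "weight": np.r_[np.full(8, 0.53), np.zeros(8)],
        })
        model = CoupledTimecourseModel(delta_bounds=(0.25, 0.5))
        model.fit(pts[["movement_time", "kind"]], pts["weight"].to_numpy())
        pred = model.predict(pts[["movement_time", "kind"]])
        np.testing.assert_allclose(pred[:8], 0.53, atol=1e-8)
        np.testing.assert_allclose(pred[8:], 0.0, atol=1e-12)

    def test_noisy_recovery_of_delay(self):
        rng = np.random.default_rng(11)
        deltas = []
        for _ in range(40):
            fit = fit_coupled_timecourse(
                self._points(**self.TRUE, noise_sd=0.05, rng=rng))
            deltas.append(fit.delta_sm)
        assert abs(np.median(deltas) - 0.277) < 0.03

    def test_too_few_points_rejected(self):
        pts = self._points(**self.TRUE).iloc[:4]
        with pytest.raises(ValueError):
            fit_coupled_timecourse(pts)


class TestErrorCoupling:
    def test_button_like_slope_and_correlation_near_one(self):
        # constant movement time: final (late-positive) error equals the
        # onset up to a constant, and the prediction error tracks it
        rng = np.random.default_rng(12)
        cfg = SimulationConfig(beta=0.7, sigma_m=0.01, sigma_x=0.0,
                               sigma_t=0.02, n_trials=360, target_time=0.8,
                               movement_time=0.33)
        s = simulate_series(cfg, rng=rng)
        from tempocorr import fit_measurement_noise

        res = fit_measurement_noise(s.onset)
        out = error_coupling_slope(res.trace.prediction_error[20:],
                                   s.error[20:])
        assert out["slope"] == pytest.approx(1.0, abs=0.2)
        assert out["correlation"] > 0.75

    def test_independent_series_slope_near_zero(self):
        rng = np.random.default_rng(13)
        out = error_coupling_slope(rng.normal(size=1000),
                                   rng.normal(size=1000))
        assert abs(out["slope"]) < 0.1

    def test_movement_time_noise_attenuates_coupling(self):
        rng = np.random.default_rng(14)
        from tempocorr import fit_measurement_noise

        def run(mt):
            cfg = SimulationConfig(beta=0.7, sigma_m=0.05, sigma_x=0.0,
                                   sigma_t=0.02, n_trials=360,
                                   target_time=0.8, movement_time=mt)
            s = simulate_series(cfg, rng=rng)
            res = fit_measurement_noise(s.onset)
            return error_coupling_slope(res.trace.prediction_error[20:],
                                        s.error[20:])

        button = run(0.33)
        arm = run(rng.normal(0.45, 0.06, 360))
        assert arm["slope"] < button["slope"]
        assert arm["correlation"] < button["correlation"]

    def test_degenerate_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            error_coupling_slope(np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            error_coupling_slope(np.ones(5), np.ones(6))

    def test_density_table_shape(self):
        rng = np.random.default_rng(15)
        out = error_coupling_slope(rng.normal(size=500),
                                   rng.normal(size=500), bins=10)
        assert out["density"].shape == (10, 10)
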