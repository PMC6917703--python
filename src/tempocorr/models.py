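"""Dependence of the action onset on the previous final error, the coupled
movement-time model of prediction- vs feedback-error weighting, and the
prediction-error/final-error coupling.

Three analyses live here:

``Lag1DependencyModel``
    Per-subject regression of the current trial's action onset on the
    previous trial's final temporal error (optionally with the previous
    trial's velocity-peak count as a covariate), pooled across subjects by
    inverse-variance weighting. The raw regression slope is *not* the
    correction fraction beta: under the generative trial-to-trial dynamics
    the population slope is beta - var(tau)/var(e), which equals beta/2
    when the planning drift is absent. A slope -> beta calibration line is
    therefore estimated from the package's own simulations
    (:func:`slope_to_beta_calibration`) and applied to turn slopes into
    feedback weights.

``CoupledTimecourseModel``
    The joint time-course of the two correction weights as a function of
    movement time Tm: the feedback weight is zero up to a sensorimotor
    delay delta_sm and rises linearly afterwards, while the prediction
    (Kalman-gain) weight decays quadratically-coupled::

        beta(Tm) = 0                      for Tm <= delta_sm
                 = b1 Tm + b0             otherwise
        K(Tm)    = sqrt(c^2 - a beta(Tm)^2)

    b0 and b1 are not free: they are eliminated by the two constraints
    beta(delta_sm) = 0 and beta(0.550 s) = (1 - c)^2, so the free
    parameters are (delta_sm, a, c), fitted by grid search over delta_sm
    (coarse-to-fine, 1 ms resolution) with nested least squares in (a, c).

``error_coupling_slope``
    OLS slope of the per-trial prediction error on the final temporal
    error. With a fixed movement time the final error is fully determined
    by the onset and the slope approaches 1; independent movement-time
    variability (online corrections) attenuates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .simulate import SimulationConfig, simulate_series

__all__ = [
    "DependencyFit",
    "Lag1DependencyModel",
    "lag1_dependency",
    "slope_to_beta_calibration",
    "CoupledModelFit",
    "CoupledTimecourseModel",
    "fit_coupled_timecourse",
    "error_coupling_slope",
]


# ---------------------------------------------------------------------------
# Lag-1 dependency on the previous final error
# ---------------------------------------------------------------------------

@dataclass
class DependencyFit:
    slope: float
    se: float
    t_value: float
    p_value: float
    per_subject: pd.DataFrame
    slope_fast: float = float("nan")
    slope_slow: float = float("nan")
    n_dropped_pairs: int = 0


class Lag1DependencyModel(BaseEstimator):
    """How much of the previous final error shows up in the current onset.

    Fits, per subject, an OLS regression of onset_i on error_{i-1} (plus
    n_peaks_{i-1} when the column is present and ``use_peaks`` is True),
    then pools the per-subject slopes with inverse-variance weights. A
    fast/slow stratification splits each subject's trials at their median
    movement time. Pairs that straddle a session boundary (``session``
    column, if present) are dropped and counted.
    """

    def __init__(self, use_peaks: bool = True, min_trials: int = 30):
        self.use_peaks = use_peaks
        self.min_trials = min_trials

    @staticmethod
    def _pairs(g: pd.DataFrame) -> pd.DataFrame:
        prev = g.shift(1)
        out = pd.DataFrame(
            {
                "onset": g["onset_s"].to_numpy(),
                "prev_error": prev["error_s"].to_numpy(),
                "movement_time": g["movement_time_s"].to_numpy(),
            }
        )
        if "n_peaks" in g.columns:
            out["prev_peaks"] = prev["n_peaks"].to_numpy()
        return out.iloc[1:]

    def _slope(self, pairs: pd.DataFrame):
        X = pairs[["prev_error"]].to_numpy()
        if self.use_peaks and "prev_peaks" in pairs.columns:
            X = np.column_stack([X, pairs["prev_peaks"].to_numpy()])
        model = sm.OLS(pairs["onset"].to_numpy(), sm.add_constant(X)).fit()
        return float(model.params[1]), float(model.bse[1])

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        required = {"subject", "onset_s", "error_s", "movement_time_s"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trial table is missing columns {sorted(missing)}")
        dropped = 0
        rows = []
        for subject, g in df.groupby("subject", sort=True):
            if len(g) < self.min_trials:
                raise ValueError(
                    f"subject {subject!r} has {len(g)} trials; need >= {self.min_trials}"
                )
            if "session" in g.columns:
                parts = [self._pairs(s) for _, s in g.groupby("session", sort=True)]
                dropped += g["session"].nunique() - 1
                pairs = pd.concat(parts, ignore_index=True)
            else:
                pairs = self._pairs(g)
            pairs = pairs.dropna()
            slope, se = self._slope(pairs)
            med = float(pairs["movement_time"].median())
            fast = pairs[pairs["movement_time"] <= med]
            slow = pairs[pairs["movement_time"] > med]
            rows.append(
                {
                    "subject": subject,
                    "slope": slope,
                    "se": se,
                    "n_pairs": len(pairs),
                    "median_movement_time": med,
                    "slope_fast": self._slope(fast)[0] if len(fast) > 10 else np.nan,
                    "slope_slow": self._slope(slow)[0] if len(slow) > 10 else np.nan,
                    "mean_movement_time": float(pairs["movement_time"].mean()),
                }
            )
        per_subject = pd.DataFrame(rows)
        w = 1.0 / per_subject["se"] ** 2
        pooled = float(np.sum(w * per_subject["slope"]) / np.sum(w))
        pooled_se = float(np.sqrt(1.0 / np.sum(w)))
        t = pooled / pooled_se
        # normal reference for the pooled z-statistic
        from scipy.stats import norm

        p = 2 * float(norm.sf(abs(t)))
        self.per_subject_ = per_subject
        self.slope_ = pooled
        self.se_ = pooled_se
        self.t_value_ = float(t)
        self.p_value_ = p
        for attr, col in (("slope_fast_", "slope_fast"),
                          ("slope_slow_", "slope_slow")):
            vals = per_subject[col].dropna()
            setattr(self, attr, float(vals.mean()) if len(vals) else float("nan"))
        self.n_dropped_pairs_ = dropped
        return self

    def result_(self) -> DependencyFit:
        return DependencyFit(
            self.slope_,
            self.se_,
            self.t_value_,
            self.p_value_,
            self.per_subject_,
            self.slope_fast_,
            self.slope_slow_,
            self.n_dropped_pairs_,
        )


def lag1_dependency(trial_table: pd.DataFrame, **kwargs) -> DependencyFit:
    """Functional wrapper around :class:`Lag1DependencyModel`."""
    return Lag1DependencyModel(**kwargs).fit(trial_table).result_()


def slope_to_beta_calibration(
    beta_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_subjects: int = 15,
    n_trials: int = 360,
    sigma_m: float = 0.05,
    sigma_movement_time: float = 0.05,
    target_time: float = 0.8,
    movement_time: float = 0.45,
    seed: int | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Estimate the line mapping observed lag-1 slopes to correction fractions.

    For every beta on the grid, multi-subject series are simulated from the
    trial-to-trial correction dynamics with movement-time variability and
    no planning drift (V_t = 0; the drift-free regime keeps beta = 0
    stationary and makes the mapping pass through the origin - analytically
    the expected slope is beta/2 in this regime). The per-beta pooled
    slopes are then regressed on beta and the inverted line
    ``beta = intercept + coef * slope`` is returned along with the
    simulated (beta, slope) table.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for beta, ss in zip(beta_grid, root.spawn(len(beta_grid))):
        frames = []
        for subj, child in enumerate(ss.spawn(n_subjects), start=1):
            rng = np.random.default_rng(child)
            mt = rng.normal(movement_time, sigma_movement_time, n_trials)
            cfg = SimulationConfig(
                beta=beta,
                sigma_m=sigma_m,
                sigma_x=0.0,
                sigma_t=0.0,
                n_trials=n_trials,
                target_time=target_time,
                movement_time=mt,
            )
            df = simulate_series(cfg, rng=rng).to_frame()
            df.insert(0, "subject", subj)
            frames.append(df)
        fit = lag1_dependency(pd.concat(frames, ignore_index=True), use_peaks=False)
        rows.append({"beta": beta, "slope": fit.slope, "se": fit.se})
    table = pd.DataFrame(rows)
    # regress beta on slope: beta_hat = intercept + coef * slope
    A = np.column_stack([np.ones(len(table)), table["slope"].to_numpy()])
    coef, *_ = np.linalg.lstsq(A, table["beta"].to_numpy(), rcond=None)
    return float(coef[0]), float(coef[1]), table


# ---------------------------------------------------------------------------
# Coupled time-course of the two correction weights
# ---------------------------------------------------------------------------

@dataclass
class CoupledModelFit:
    delta_sm: float
    a: float
    c: float
    b0: float
    b1: float
    r2: float
    sse: float
    residual_profile: pd.DataFrame = field(default=None, repr=False)


def _beta_t(tm: np.ndarray, delta_sm: float, c: float, t_ref: float) -> np.ndarray:
    """Feedback weight as a function of movement time (constrained line)."""
    b1 = (1.0 - c) ** 2 / (t_ref - delta_sm)
    return np.where(tm <= delta_sm, 0.0, b1 * (tm - delta_sm))


def _k_t(tm: np.ndarray, delta_sm: float, a: float, c: float, t_ref: float) -> np.ndarray:
    beta = _beta_t(tm, delta_sm, c, t_ref)
    return np.sqrt(np.clip(c ** 2 - a * beta ** 2, 0.0, None))


class CoupledTimecourseModel(BaseEstimator):
    """Joint fit of the prediction-weight decay and feedback-weight rise.

    Input points are per-subject (movement time, weight) observations of
    two kinds: Kalman-gain contributions (kind ``"K"``) and feedback-based
    weights (kind ``"beta"``). ``fit(X, y)`` expects ``X`` with columns
    ``movement_time`` and ``kind`` (a DataFrame, or an (n, 2) array with
    kind coded 0 for K and 1 for beta) and ``y`` the observed weights.

    The sensorimotor delay is found by grid search (coarse step then a
    1 ms refinement; the piecewise boundary makes the objective non-smooth
    in delta_sm) with (a, c) fitted by nested least squares at each
    candidate, warm-started from the previous grid point. Residuals of the
    K and beta point sets are weighted equally.
    """

    def __init__(
        self,
        delta_bounds: tuple = (0.1, 0.5),
        coarse_step: float = 0.01,
        fine_step: float = 0.001,
        t_ref: float = 0.550,
    ):
        self.delta_bounds = delta_bounds
        self.coarse_step = coarse_step
        self.fine_step = fine_step
        self.t_ref = t_ref

    @staticmethod
    def _unpack(X):
        if isinstance(X, pd.DataFrame):
            tm = X["movement_time"].to_numpy(dtype=float)
            kind = X["kind"].to_numpy()
            is_beta = np.asarray([k in (1, "beta") for k in kind])
        else:
            X = np.asarray(X, dtype=float)
            tm = X[:, 0]
            is_beta = X[:, 1] > 0.5
        return tm, is_beta

    def _residuals(self, params, delta, tm, is_beta, y):
        a, c = params
        pred = np.where(
            is_beta,
            _beta_t(tm, delta, c, self.t_ref),
            _k_t(tm, delta, a, c, self.t_ref),
        )
        return pred - y

    def _fit_delta(self, delta, tm, is_beta, y, x0):
        res = least_squares(
            self._residuals,
            x0,
            args=(delta, tm, is_beta, y),
            bounds=([0.0, 1e-6], [50.0, 1.0]),
            method="trf",
        )
        return res.x, float(np.sum(res.fun ** 2))

    def fit(self, X, y):
        tm, is_beta = self._unpack(X)
        y = np.asarray(y, dtype=float)
        if tm.size < 6:
            raise ValueError("need at least 6 points to fit the coupled model")
        lo, hi = self.delta_bounds
        hi = min(hi, self.t_ref - 1e-3)

        def scan(grid, x0):
            best = (None, None, np.inf)
            x = x0
            profile = []
            for d in grid:
                x, sse = self._fit_delta(d, tm, is_beta, y, x)
                profile.append((d, sse))
                if sse < best[2] - 1e-15:
                    best = (d, x.copy(), sse)
            return best, profile

        coarse = np.arange(lo, hi + 1e-12, self.coarse_step)
        x0 = np.array([1.0, max(np.mean(y[~is_beta]) if (~is_beta).any() else 0.5, 0.05)])
        (d0, x_best, _), prof1 = scan(coarse, x0)
        if d0 is None:
            raise RuntimeError(f"coupled-model fit failed; profile: {prof1}")
        fine = np.arange(
            max(lo, d0 - self.coarse_step),
            min(hi, d0 + self.coarse_step) + 1e-12,
            self.fine_step,
        )
        (d_best, x_best, sse), prof2 = scan(fine, x_best)
        a, c = float(x_best[0]), float(x_best[1])
        b1 = (1.0 - c) ** 2 / (self.t_ref - d_best)
        tss = float(np.sum((y - y.mean()) ** 2))
        self.delta_sm_ = float(d_best)
        self.a_ = a
        self.c_ = c
        self.b1_ = float(b1)
        self.b0_ = float(-b1 * d_best)
        self.sse_ = float(sse)
        self.r2_ = 1.0 - sse / tss if tss > 0 else float("nan")
        self.residual_profile_ = pd.DataFrame(
            prof1 + prof2, columns=["delta_sm", "sse"]
        )
        return self

    def predict(self, X):
        tm, is_beta = self._unpack(X)
        return np.where(
            is_beta,
            _beta_t(tm, self.delta_sm_, self.c_, self.t_ref),
            _k_t(tm, self.delta_sm_, self.a_, self.c_, self.t_ref),
        )

    def result_(self) -> CoupledModelFit:
        return CoupledModelFit(
            self.delta_sm_,
            self.a_,
            self.c_,
            self.b0_,
            self.b1_,
            self.r2_,
            self.sse_,
            self.residual_profile_,
        )


def fit_coupled_timecourse(points: pd.DataFrame, **kwargs) -> CoupledModelFit:
    """Fit the coupled model to a points table.

    ``points`` needs columns ``movement_time``, ``kind`` ("K" or "beta")
    and ``weight``.
    """
    model = CoupledTimecourseModel(**kwargs)
    model.fit(points[["movement_time", "kind"]], points["weight"].to_numpy())
    return model.result_()


# ---------------------------------------------------------------------------
# Prediction-error / final-error coupling
# ---------------------------------------------------------------------------

def error_coupling_slope(
    prediction_errors: np.ndarray,
    final_errors: np.ndarray,
    error_convention: str = "early_positive",
    bins: int = 25,
) -> dict:
    """OLS slope of the prediction error on the final temporal error.

    The prediction error is Ts - tau (positive = later than planned). The
    final error is flipped to the late-positive axis when it arrives in the
    early-positive convention of the simulator tables
    (``error_convention="early_positive"``), so that in the deterministic
    limit (constant movement time, no online correction) the two errors
    coincide and the slope is 1. Returns the slope, Pearson correlation,
    and a binned 2-D density table.
    """
    pe = np.asarray(prediction_errors, dtype=float)
    fe = np.asarray(final_errors, dtype=float)
    if pe.size != fe.size:
        raise ValueError("paired series must have equal length")
    if error_convention == "early_positive":
        fe = -fe
    elif error_convention != "late_positive":
        raise ValueError(f"unknown error convention {error_convention!r}")
    if np.var(fe) == 0 or np.var(pe) == 0:
        raise ValueError("degenerate variance in one of the error series")
    slope, intercept = np.polyfit(fe, pe, 1)
    r = float(np.corrcoef(fe, pe)[0, 1])
    H, xe, ye = np.histogram2d(fe, pe, bins=bins, density=True)
    density = pd.DataFrame(
        H, index=pd.Index(0.5 * (xe[:-1] + xe[1:]), name="final_error"),
        columns=pd.Index(0.5 * (ye[:-1] + ye[1:]), name="prediction_error"),
    )
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "correlation": r,
        "density": density,
        "n": int(pe.size),
    }
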