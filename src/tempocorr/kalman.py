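"""Kalman-filter estimation of the latent planned action onset.

The observed onset series ``Ts_i`` is modelled as a noisy reading of a
latent planned onset ``tau_i`` that drifts with process variance ``V_t``:

    tau prior:    P_i   = Phat_{i-1} + V_t,i
    gain:         K_i   = P_i / (P_i + sigma_m^2)
    posterior:    tauhat_i = tau_i + K_i (Ts_i - tau_i)
    post. var:    Phat_i = (1 - K_i) P_i

The posterior becomes the prior planned onset of the next trial. The
*prediction error* of trial i is ``Ts_i - tau_i``, the discrepancy between
the actual and the planned onset; the Kalman gain is the fraction of this
error carried into the next plan. The execution-noise variance
``sigma_m^2`` is the single free parameter; the per-trial process variance
is estimated from a trailing 4-trial moving window of the observed onsets.

Identification of ``sigma_m^2``: the raw sum of squared one-step prediction
errors is monotone in ``sigma_m`` on stationary (well-corrected) onset
series - shrinking the gain towards zero makes the prior a running mean,
which is the best mean-square one-step predictor of any mean-reverting
series - so that criterion cannot identify the parameter. The least-squares
criterion is therefore applied to the *squared* prediction errors against
their filter-implied innovation variances ``P_i + sigma_m^2``: the fitted
``sigma_m^2`` makes the filter's predicted uncertainty agree with the
realized one-step errors. On a correctly specified random-walk-plus-noise
series this estimating equation is consistent; its behavior on
feedback-corrected series is characterized in the package's tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "PlannedStateTrace",
    "KalmanFitResult",
    "static_gain",
    "steady_state_gain",
    "estimate_process_variance",
    "kalman_filter",
    "KalmanGainEstimator",
    "fit_measurement_noise",
]


def static_gain(vt: float, sigma_m2: float) -> float:
    """One-step Kalman gain ``V_t / (V_t + sigma_m^2)``.

    This is the gain of a filter whose prior variance equals the process
    variance (no accumulated uncertainty). Raises if both variances are zero
    (the gain is then undefined).
    """
    if vt < 0 or sigma_m2 < 0:
        raise ValueError("variances must be non-negative")
    if vt == 0 and sigma_m2 == 0:
        raise ValueError("gain undefined when both variances are zero")
    return vt / (vt + sigma_m2)


def steady_state_gain(vt: float, sigma_m2: float) -> float:
    """Steady-state gain of the scalar random-walk-plus-noise filter.

    Solves the scalar Riccati fixed point: the steady prior variance M
    satisfies M = (1 - K) M + V_t with K = M / (M + sigma_m^2), equivalently
    K^2 sigma_m^2 = V_t (1 - K). For sigma_m = 0 this is 1. The
    variance-minimizing constant correction fraction of the generative model
    equals this gain (not the one-step :func:`static_gain`).
    """
    if vt < 0 or sigma_m2 < 0:
        raise ValueError("variances must be non-negative")
    if vt == 0 and sigma_m2 == 0:
        raise ValueError("gain undefined when both variances are zero")
    if sigma_m2 == 0:
        return 1.0
    # positive root of sigma_m2 K^2 + vt K - vt = 0
    return (-vt + np.sqrt(vt * vt + 4.0 * sigma_m2 * vt)) / (2.0 * sigma_m2)


def estimate_process_variance(onsets: np.ndarray, window: int = 4) -> np.ndarray:
    """Per-trial process-variance estimates from a trailing moving window.

    The estimate for trial ``i`` is the sample variance (n-1 normalization)
    of the ``window`` onsets ending at trial ``i - 1``, so the prior for
    trial ``i`` never uses the observation it will be compared against. The
    first trials, for which no full trailing window exists, receive the
    first computable value.
    """
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    if n < window:
        raise ValueError(f"series length {n} is shorter than the window {window}")
    vt = np.empty(n)
    first = float(np.var(onsets[:window], ddof=1))
    vt[: window] = first
    for i in range(window, n):
        vt[i] = np.var(onsets[i - window : i], ddof=1)
    return vt


@dataclass
class PlannedStateTrace:
    """Per-trial filter quantities (all arrays share one length)."""

    tau_prior: np.ndarray
    P_prior: np.ndarray
    gain: np.ndarray
    tau_post: np.ndarray
    P_post: np.ndarray
    prediction_error: np.ndarray

    def __len__(self) -> int:
        return self.tau_prior.size


def kalman_filter(
    onsets: np.ndarray,
    sigma_m2: float,
    vt_series: np.ndarray | float,
    tau0: float | None = None,
    P0: float | None = None,
) -> PlannedStateTrace:
    """Run the scalar filter over an onset series.

    ``tau0``/``P0`` are the prior mean and variance at the first trial; they
    default to the first observation and the mean of ``vt_series`` (so the
    first-trial gain is close to the one-step static gain). ``vt_series``
    may be a scalar (constant process noise) or a per-trial array.
    """
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    vt = np.broadcast_to(np.asarray(vt_series, dtype=float), (n,))
    if sigma_m2 < 0 or np.any(vt < 0):
        raise ValueError("variances must be non-negative")
    if tau0 is None:
        tau0 = float(onsets[0])
    if P0 is None:
        P0 = float(np.mean(vt))

    tau_prior = np.empty(n)
    P_prior = np.empty(n)
    gain = np.empty(n)
    tau_post = np.empty(n)
    P_post = np.empty(n)
    tau, P = float(tau0), float(P0)
    for i in range(n):
        if i > 0:
            P = P_post[i - 1] + vt[i]
        denom = P + sigma_m2
        K = P / denom if denom > 0 else 0.0
        tau_prior[i] = tau
        P_prior[i] = P
        gain[i] = K
        tau = tau + K * (onsets[i] - tau)
        tau_post[i] = tau
        P_post[i] = (1.0 - K) * P
    return PlannedStateTrace(
        tau_prior, P_prior, gain, tau_post, P_post, onsets - tau_prior
    )


@dataclass
class KalmanFitResult:
    sigma_m2: float
    sigma_m: float
    mean_gain: float
    steady_gain: float
    sse: float
    trace: PlannedStateTrace
    vt_series: np.ndarray
    objective_profile: tuple = field(default=(), repr=False)


class KalmanGainEstimator(BaseEstimator):
    """Fit the execution-noise SD of the planned-onset filter to a series.

    The only free parameter is ``sigma_m`` (s). For each candidate the
    filter is run with the per-trial process variances (the windowed
    estimates by default, or a known value passed as ``vt``) and the
    least-squares discrepancy between the squared one-step prediction
    errors and their filter-implied variances (after ``burn_in`` trials) is
    minimized by bounded scalar search over three sub-intervals of
    ``sigma_m_bounds`` (restarts guard against local minima near the
    bounds). ``objective="sse"`` selects the raw sum of squared prediction
    errors instead (degenerate on stationary series; see the module
    docstring).

    Attributes (after :meth:`fit`)
    ------------------------------
    sigma_m_, sigma_m2_ : fitted execution-noise SD / variance.
    mean_gain_ : trial-average Kalman gain after burn-in.
    steady_gain_ : steady-state gain at the mean process variance (the
        per-subject "Kalman gain" can be read either way; both are kept).
    sse_ : minimized sum of squared one-step prediction errors (s^2).
    trace_ : :class:`PlannedStateTrace` at the fitted parameter.
    vt_series_ : windowed per-trial process-variance estimates.
    """

    def __init__(
        self,
        window: int = 4,
        sigma_m_bounds: tuple = (1e-4, 1.0),
        burn_in: int = 5,
        xatol: float = 1e-10,
        vt: float | np.ndarray | None = None,
        objective: str = "innovation_matching",
    ):
        self.window = window
        self.sigma_m_bounds = sigma_m_bounds
        self.burn_in = burn_in
        self.xatol = xatol
        self.vt = vt
        self.objective = objective

    def _loss(self, sigma_m: float, onsets, vt) -> float:
        trace = kalman_filter(onsets, sigma_m ** 2, vt)
        pe = trace.prediction_error[self.burn_in :]
        if self.objective == "sse":
            return float(np.sum(pe * pe))
        S = trace.P_prior[self.burn_in :] + sigma_m ** 2
        d = pe * pe - S
        return float(np.sum(d * d))

    def fit(self, X, y=None):
        if self.objective not in ("innovation_matching", "sse"):
            raise ValueError(f"unknown objective {self.objective!r}")
        onsets = np.asarray(X, dtype=float).ravel()
        if onsets.size < 10:
            raise ValueError("need at least 10 trials to fit the filter")
        if self.vt is None:
            vt = estimate_process_variance(onsets, window=self.window)
        else:
            vt = np.broadcast_to(np.asarray(self.vt, dtype=float), onsets.shape).copy()
        lo, hi = self.sigma_m_bounds
        # three overlapping brackets = cheap restarts
        brackets = [(lo, 0.12), (0.08, 0.45), (0.3, hi)]
        brackets = [(max(a, lo), min(b, hi)) for a, b in brackets if a < hi and b > lo]
        profile = []
        best = None
        for a, b in brackets:
            res = minimize_scalar(
                self._loss,
                bounds=(a, b),
                args=(onsets, vt),
                method="bounded",
                options={"xatol": self.xatol},
            )
            profile.append((a, b, float(res.x), float(res.fun)))
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(
                f"measurement-noise optimization failed; profile: {profile}"
            )
        sigma_m = float(best.x)
        trace = kalman_filter(onsets, sigma_m ** 2, vt)
        self.sigma_m_ = sigma_m
        self.sigma_m2_ = sigma_m ** 2
        self.trace_ = trace
        self.vt_series_ = vt
        self.mean_gain_ = float(np.mean(trace.gain[self.burn_in :]))
        self.steady_gain_ = steady_state_gain(float(np.mean(vt)), sigma_m ** 2)
        pe = trace.prediction_error[self.burn_in :]
        self.sse_ = float(np.sum(pe * pe))
        self.loss_ = float(best.fun)
        self.objective_profile_ = tuple(profile)
        return self

    def predict(self, X):
        """One-step prior predictions of the planned onset for a series."""
        onsets = np.asarray(X, dtype=float).ravel()
        vt = estimate_process_variance(onsets, window=self.window)
        return kalman_filter(onsets, self.sigma_m2_, vt).tau_prior

    def result_(self) -> KalmanFitResult:
        return KalmanFitResult(
            self.sigma_m2_,
            self.sigma_m_,
            self.mean_gain_,
            self.steady_gain_,
            self.sse_,
            self.trace_,
            self.vt_series_,
            self.objective_profile_,
        )


def fit_measurement_noise(onsets: np.ndarray, **kwargs) -> KalmanFitResult:
    """Functional wrapper around :class:`KalmanGainEstimator`."""
    return KalmanGainEstimator(**kwargs).fit(onsets).result_()
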