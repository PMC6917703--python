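"""Generative model of interception-timing trial series and synthetic kinematics.

The simulator implements a trial-to-trial correction process for the planned
action onset. On trial ``i`` the actor holds a planned onset ``tau_i`` (s,
relative to target motion onset). The actual onset is the plan corrupted by
execution noise, the final temporal error is measured at the interception
zone, and a fraction ``beta`` of that error is fed back into the next plan,
on top of a random planning drift::

    Ts_i      = tau_i + r,            r ~ N(0, sigma_m^2)      (execution)
    e_i       = T_T - (Ts_i + Tm_i)                            (final error)
    tau_{i+1} = tau_i + beta * e_i + q,  q ~ N(0, V_t)         (correction + drift)

Sign convention: ``e_i > 0`` means the effector arrived *early* (onset +
movement time shorter than the target's time-to-contact); a positive error
therefore pushes the next planned onset later, which is the corrective
direction.

The planning-noise variance has a velocity-dependent and a timing component::

    V_t = (sigma_x / v)^2 + sigma_t^2

with ``sigma_x`` the spatial uncertainty about the target (cm), ``v`` the
target speed (cm/s) and ``sigma_t`` a speed-independent timing SD (s).

Units are seconds and centimetres throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedSeries",
    "KinematicTrace",
    "planning_variance",
    "mean_planning_variance",
    "simulate_series",
    "simulate_batch",
    "generate_kinematic_trace",
    "generate_experiment_dataset",
]

#: Target speeds used in the interleaved-speed sessions (cm/s).
DEFAULT_SPEEDS = (20.0, 25.0, 30.0)

#: Trials discarded before computing summary statistics (start-up transient).
DEFAULT_BURN_IN = 20


def planning_variance(sigma_x: float, sigma_t: float, speed: float) -> float:
    """Planning (process) noise variance ``V_t`` for one target speed.

    Parameters
    ----------
    sigma_x : spatial uncertainty about the target position (cm).
    sigma_t : timing uncertainty (s).
    speed : target speed (cm/s); must be strictly positive.

    Returns
    -------
    float
        ``(sigma_x / speed)**2 + sigma_t**2`` in s^2.
    """
    if speed <= 0:
        raise ValueError(f"target speed must be positive, got {speed}")
    if sigma_x < 0 or sigma_t < 0:
        raise ValueError("noise SDs must be non-negative")
    return (sigma_x / speed) ** 2 + sigma_t ** 2


def mean_planning_variance(
    sigma_x: float, sigma_t: float, speeds: Sequence[float]
) -> float:
    """Arithmetic mean of :func:`planning_variance` over a list of speeds."""
    speeds = tuple(speeds)
    if not speeds:
        raise ValueError("speeds must be non-empty")
    return float(np.mean([planning_variance(sigma_x, sigma_t, v) for v in speeds]))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated trial series.

    ``movement_time`` may be a scalar (constant movement time) or a
    per-trial sequence of length ``n_trials`` (e.g. to emulate online
    movement-time variability).  ``vt_mode`` selects whether the planning
    noise is drawn with the current trial's speed-specific variance
    (``"per_trial"``) or with the mean variance over the speed list
    (``"mean"``, the default used for the optimality simulation study).
    """

    beta: float = 0.5
    sigma_m: float = 0.05
    sigma_x: float = 1.0
    sigma_t: float = 0.05
    speeds: tuple = DEFAULT_SPEEDS
    n_trials: int = 360
    n_reps: int = 1
    target_time: float = 0.0
    movement_time: float | Sequence[float] = 0.0
    seed: int | None = None
    vt_mode: str = "mean"
    tau0: float | None = None  # initial planned onset; default error-free

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        for name in ("sigma_m", "sigma_x", "sigma_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.speeds) == 0 or any(v <= 0 for v in self.speeds):
            raise ValueError("speeds must be non-empty and strictly positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")
        if self.vt_mode not in ("mean", "per_trial"):
            raise ValueError(f"unknown vt_mode {self.vt_mode!r}")
        mt = np.asarray(self.movement_time, dtype=float)
        if mt.ndim not in (0, 1):
            raise ValueError("movement_time must be scalar or 1-D")
        if mt.ndim == 1 and mt.size != self.n_trials:
            raise ValueError("per-trial movement_time must have length n_trials")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @property
    def mean_vt(self) -> float:
        return mean_planning_variance(self.sigma_x, self.sigma_t, self.speeds)


@dataclass
class SimulatedSeries:
    """One simulated trial series with its latent ground truth."""

    tau: np.ndarray        # planned onsets (s), latent
    onset: np.ndarray      # actual onsets Ts (s)
    error: np.ndarray      # final temporal errors e (s), positive = early
    speed: np.ndarray      # per-trial target speed (cm/s)
    movement_time: np.ndarray
    config: SimulationConfig

    def __len__(self) -> int:
        return self.onset.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "speed": self.speed,
                "onset_s": self.onset,
                "movement_time_s": self.movement_time,
                "error_s": self.error,
                "tau_s": self.tau,  # ground truth, not observable in experiments
            }
        )


def _movement_times(config: SimulationConfig) -> np.ndarray:
    mt = np.asarray(config.movement_time, dtype=float)
    if mt.ndim == 0:
        return np.full(config.n_trials, float(mt))
    return mt.copy()


def simulate_series(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedSeries:
    """Simulate one trial series from the generative model.

    The planned onset starts at the error-free value ``T_T - mean(T_m)`` so
    that any constant offset is absent by construction; with ``beta > 0`` any
    residual transient decays and a burn-in of :data:`DEFAULT_BURN_IN` trials
    is discarded by downstream summary statistics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials
    speeds = np.asarray(config.speeds, dtype=float)
    speed = speeds[rng.integers(0, speeds.size, size=n)]
    if config.vt_mode == "per_trial":
        vt = (config.sigma_x / speed) ** 2 + config.sigma_t ** 2
    else:
        vt = np.full(n, config.mean_vt)
    r = rng.normal(0.0, config.sigma_m, size=n)
    q = rng.normal(0.0, 1.0, size=n) * np.sqrt(vt)
    mts = _movement_times(config)

    tau = np.empty(n)
    onset = np.empty(n)
    error = np.empty(n)
    tau_i = (config.target_time - float(np.mean(mts))
             if config.tau0 is None else float(config.tau0))
    for i in range(n):
        tau[i] = tau_i
        onset[i] = tau_i + r[i]
        error[i] = config.target_time - (onset[i] + mts[i])
        tau_i = tau_i + config.beta * error[i] + q[i]
    return SimulatedSeries(tau, onset, error, speed, mts, config)


def simulate_batch(
    config: SimulationConfig,
    n_reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate many replicate series at once (vectorized over replicates).

    Returns ``(tau, onset, error)`` arrays of shape ``(n_reps, n_trials)``.
    Used by the simulation study where thousands of replicate series are
    needed; statistically equivalent to repeated :func:`simulate_series`
    calls but draws noise in a different order, so replicate k here is not
    bit-identical to the k-th single-series call.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_reps is None:
        n_reps = config.n_reps
    n = config.n_trials
    speeds = np.asarray(config.speeds, dtype=float)
    speed = speeds[rng.integers(0, speeds.size, size=(n_reps, n))]
    if config.vt_mode == "per_trial":
        vt = (config.sigma_x / speed) ** 2 + config.sigma_t ** 2
    else:
        vt = np.full((n_reps, n), config.mean_vt)
    r = rng.normal(0.0, config.sigma_m, size=(n_reps, n))
    q = rng.normal(0.0, 1.0, size=(n_reps, n)) * np.sqrt(vt)
    mts = _movement_times(config)

    tau = np.empty((n_reps, n))
    onset = np.empty((n_reps, n))
    error = np.empty((n_reps, n))
    tau_i = np.full(
        n_reps,
        config.target_time - float(np.mean(mts))
        if config.tau0 is None else float(config.tau0),
    )
    for i in range(n):
        tau[:, i] = tau_i
        onset[:, i] = tau_i + r[:, i]
        error[:, i] = config.target_time - (onset[:, i] + mts[i])
        tau_i = tau_i + config.beta * error[:, i] + q[:, i]
    return tau, onset, error


# ---------------------------------------------------------------------------
# Synthetic kinematics
# ---------------------------------------------------------------------------

@dataclass
class KinematicTrace:
    """A synthetic position trace with known ground truth."""

    t: np.ndarray
    x: np.ndarray
    true_onset: float
    n_submovements: int
    noise_sd: float

    def __post_init__(self):
        if self.t.size < 3:
            raise ValueError("trace must have at least 3 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("sample times must be strictly increasing and uniform")

    @property
    def rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def _minimum_jerk_position(phase: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on phase in [0, 1]."""
    p = np.clip(phase, 0.0, 1.0)
    return 10 * p ** 3 - 15 * p ** 4 + 6 * p ** 5


def generate_kinematic_trace(
    true_onset: float,
    movement_time: float,
    amplitude: float = 15.0,
    n_submovements: int = 1,
    noise_sd: float = 0.0,
    rate: float = 125.0,
    total_duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> KinematicTrace:
    """Generate a position trace: flat baseline, then bell-shaped movement(s).

    The primary movement is a minimum-jerk reach of the given amplitude. If
    ``n_submovements > 1``, smaller corrective sub-movements are appended
    late in the reach so that the speed profile has exactly that many local
    maxima in the noiseless case.

    Parameters
    ----------
    true_onset : ground-truth movement onset (s).
    movement_time : total duration of the movement, including corrective
        sub-movements (s); must be positive.
    amplitude : total displacement (cm).
    n_submovements : number of velocity peaks to build in (>= 1).
    noise_sd : SD of additive Gaussian position noise (cm).
    rate : sampling rate (Hz).
    total_duration : trace length (s); defaults to onset + movement_time
        + 0.2 s of trailing plateau.
    """
    if n_submovements < 1:
        raise ValueError("n_submovements must be >= 1")
    if movement_time <= 0:
        raise ValueError("movement_time must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if total_duration is None:
        total_duration = true_onset + movement_time + 0.2
    n = int(round(total_duration * rate)) + 1
    t = np.arange(n) / rate
    x = np.zeros(n)

    if n_submovements == 1:
        segments = [(true_onset, movement_time, amplitude)]
    else:
        # Primary reach covers 70% of the duration and 85% of the amplitude;
        # the remainder is split into equal back-to-back corrective segments.
        primary_T = 0.7 * movement_time
        rest_T = (movement_time - primary_T) / (n_submovements - 1)
        primary_A = 0.85 * amplitude
        rest_A = (amplitude - primary_A) / (n_submovements - 1)
        segments = [(true_onset, primary_T, primary_A)]
        start = true_onset + primary_T
        for _ in range(n_submovements - 1):
            segments.append((start, rest_T, rest_A))
            start += rest_T
    for start, dur, amp in segments:
        x += amp * _minimum_jerk_position((t - start) / dur)

    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return KinematicTrace(t, x, true_onset, n_submovements, noise_sd)


# ---------------------------------------------------------------------------
# Experiment emulation
# ---------------------------------------------------------------------------

#: Per-condition constants of the three interception tasks. ``target_time``
#: is the time-to-contact of the target with the interception zone.
CONDITIONS = {
    "arm": dict(target_time=0.8, n_trials=360, sigma_m=0.05, beta=0.4,
                p_extra_peak=0.39),
    "button": dict(target_time=0.8, n_trials=360, sigma_m=0.076, beta=0.45,
                   movement_time=0.330, p_extra_peak=0.0),
    "eye": dict(target_time=0.6, n_trials=390, sigma_m=0.075, beta=0.45,
                movement_time=0.052, p_extra_peak=0.28),
}

#: Absolute final error below which a trial counts as a hit (s).
HIT_THRESHOLD = 0.020


def generate_experiment_dataset(
    condition: str,
    n_subjects: int = 15,
    seed: int | None = None,
    sigma_movement_time: float = 0.02,
    **overrides,
) -> pd.DataFrame:
    """Emulate a multi-subject session of one of the three interception tasks.

    Conditions differ only through parameters: trial count and time-to-contact,
    the movement-time distribution (button: constant 330 ms cursor flight;
    eye: ~52 ms saccades; arm: subject-specific means drawn in 0.3-0.6 s with
    trial-to-trial variability), execution-noise level and correction
    fraction. Keyword overrides are applied to every subject's
    :class:`SimulationConfig` (e.g. ``sigma_m=0`` for a noise-free table).

    Returns a trial table with one row per trial and a ``tau_s`` ground-truth
    column.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
        )
    spec = dict(CONDITIONS[condition])
    n_trials = int(overrides.pop("n_trials", spec["n_trials"]))
    p_extra = overrides.pop("p_extra_peak", spec["p_extra_peak"])
    root = np.random.SeedSequence(seed)
    frames = []
    for subj, child in enumerate(root.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        if condition == "arm":
            mt_mean = rng.uniform(0.3, 0.6)
            mt = np.maximum(rng.normal(mt_mean, sigma_movement_time, n_trials), 0.05)
        else:
            mt = np.full(n_trials, spec["movement_time"])
        cfg = SimulationConfig(
            beta=overrides.get("beta", spec["beta"]),
            sigma_m=overrides.get("sigma_m", spec["sigma_m"]),
            sigma_x=overrides.get("sigma_x", 1.0),
            sigma_t=overrides.get("sigma_t", 0.05),
            speeds=tuple(overrides.get("speeds", DEFAULT_SPEEDS)),
            n_trials=n_trials,
            target_time=overrides.get("target_time", spec["target_time"]),
            movement_time=mt,
            vt_mode=overrides.get("vt_mode", "per_trial"),
        )
        series = simulate_series(cfg, rng=rng)
        n_peaks = 1 + (rng.random(n_trials) < p_extra).astype(int)
        df = series.to_frame()
        df.insert(0, "condition", condition)
        df.insert(0, "subject", subj)
        df["n_peaks"] = n_peaks
        df["hit"] = (np.abs(df["error_s"]) < HIT_THRESHOLD).astype(int)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
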