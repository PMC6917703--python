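"""Kinematic preprocessing: filtering, differentiation, onset detection,
velocity-peak counting and saccade validity rules.

The processing chain for a raw position trace is: zero-phase low-pass
filtering (4th-order Butterworth, 8 Hz cut-off, applied forward and
backward), three-point central-difference speed, backward-iterative onset
detection from a fraction of peak speed, and counting of speed-profile local
maxima as a marker of corrective sub-movements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpeedProfile",
    "lowpass_filter",
    "velocity",
    "detect_onset",
    "count_velocity_peaks",
    "validate_saccade",
    "preprocess_trace",
]

#: Online saccade-trigger velocity threshold (deg/s). Recorded for reference;
#: only the offline validity rule below is applied to data tables.
ONLINE_SACCADE_VELOCITY_THRESHOLD = 74.0
#: Offline Eyelink detection thresholds (deg/s, deg/s^2).
OFFLINE_SACCADE_VELOCITY_THRESHOLD = 30.0
OFFLINE_SACCADE_ACCELERATION_THRESHOLD = 8000.0

#: Saccade validity rule: discard if amplitude gain < this value ...
MIN_SACCADE_GAIN = 0.5
#: ... or duration longer than this (s). Both comparisons are strict.
MAX_SACCADE_DURATION = 0.100


@dataclass
class SpeedProfile:
    """Speed magnitude on a uniform time grid."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if np.any(self.v < 0):
            raise ValueError("speed must be non-negative")

    @property
    def peak_speed(self) -> float:
        return float(np.max(self.v))

    @property
    def sample_period(self) -> float:
        return float(self.t[1] - self.t[0])


def lowpass_filter(
    x: np.ndarray, rate: float, order: int = 4, cutoff_hz: float = 8.0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The bidirectional pass squares the magnitude response, so the effective
    attenuation at frequency f is 1 / (1 + (f / cutoff)^(2*order)). Length is
    preserved; edges are handled by reflective padding.
    """
    x = np.asarray(x, dtype=float)
    nyquist = rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, padtype="even")


def velocity(t: np.ndarray, x: np.ndarray) -> SpeedProfile:
    """Speed from position by three-point central differences.

    Interior samples use ``|x[k+1] - x[k-1]| / (2 dt)``; the endpoints use
    one-sided differences.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = t[1] - t[0]
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return SpeedProfile(t, np.abs(v))


def detect_onset(profile: SpeedProfile, fraction: float = 0.10) -> float:
    """Movement onset by the backward-iterative threshold algorithm.

    (a) Find the first sample whose speed reaches ``fraction`` of the peak
    speed. (b) Step backwards from there; at each step the tolerance is
    updated to ``fraction`` times the current sample's speed, and the walk
    stops at the first earlier sample whose speed falls below the current
    tolerance. That sample's time is the onset. If the walk reaches the
    first sample without stopping, the first sample's time is returned.
    """
    v = profile.v
    peak = profile.peak_speed
    if peak <= 0:
        raise ValueError("cannot detect onset on an all-zero speed profile")
    start = int(np.argmax(v >= fraction * peak))
    j = start
    tol = fraction * v[j]
    while j > 0:
        if v[j - 1] < tol:
            return float(profile.t[j - 1])
        j -= 1
        tol = fraction * v[j]
    return float(profile.t[0])


def count_velocity_peaks(
    profile: SpeedProfile,
    min_prominence: float | None = None,
    onset: float | None = None,
    crossing_time: float | None = None,
) -> int:
    """Number of local speed maxima between onset and target-line crossing.

    A "peak" is a local maximum with prominence of at least
    ``min_prominence`` (default: 5% of the profile's peak speed, a
    noise-robustness choice). Peaks occurring after ``crossing_time`` are
    not counted, so a movement whose first peak falls after the crossing
    yields zero peaks.
    """
    if min_prominence is None:
        min_prominence = 0.05 * profile.peak_speed
    idx, _ = signal.find_peaks(profile.v, prominence=min_prominence)
    times = profile.t[idx]
    if onset is not None:
        times = times[times >= onset]
    if crossing_time is not None:
        times = times[times <= crossing_time]
    return int(times.size)


def validate_saccade(amplitude_gain: float, duration_s: float) -> bool:
    """Offline saccade validity rule: ``True`` means keep the trial.

    A saccade is discarded iff its amplitude gain is smaller than 0.5 or its
    duration exceeds 100 ms (strict inequalities: a gain of exactly 0.5 and
    a duration of exactly 100 ms are both kept).
    """
    if duration_s < 0:
        raise ValueError("saccade duration cannot be negative")
    return not (amplitude_gain < MIN_SACCADE_GAIN or duration_s > MAX_SACCADE_DURATION)


def preprocess_trace(
    t: np.ndarray,
    x: np.ndarray,
    rate: float | None = None,
    fraction: float = 0.10,
    crossing_time: float | None = None,
    min_prominence: float | None = None,
) -> dict:
    """Full preprocessing of one raw trace.

    Filters the positions, differentiates, detects the movement onset and
    counts velocity peaks. Returns a dict with ``onset_s``, ``peak_speed``,
    ``n_peaks``, ``movement_time_s`` (onset to ``crossing_time`` when the
    latter is given, else NaN) and the :class:`SpeedProfile`.
    """
    t = np.asarray(t, dtype=float)
    if rate is None:
        rate = 1.0 / (t[1] - t[0])
    xf = lowpass_filter(x, rate=rate)
    prof = velocity(t, xf)
    onset = detect_onset(prof, fraction=fraction)
    n_peaks = count_velocity_peaks(
        prof, min_prominence=min_prominence, onset=onset, crossing_time=crossing_time
    )
    movement_time = crossing_time - onset if crossing_time is not None else float("nan")
    return {
        "onset_s": onset,
        "peak_speed": prof.peak_speed,
        "n_peaks": n_peaks,
        "movement_time_s": movement_time,
        "profile": prof,
    }
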