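"""Lag-1 autocorrelation diagnostics and the correction-optimality study.

Rationale: the planned onset drifts as a random walk (planning noise), so
with no trial-to-trial correction (beta = 0) errors accumulate and the
lag-1 autocorrelation acf(1) of the final errors is positive. With full
correction (beta = 1) every execution-noise realization is over-corrected
and consecutive errors land on opposite sides of the mean: acf(1) is
negative. The correction fraction that minimizes the error variance sits in
between and leaves acf(1) at zero, so acf(1) classifies a series as
under-correcting, over-correcting or near-optimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kalman import static_gain, steady_state_gain
from .simulate import DEFAULT_BURN_IN, SimulationConfig, simulate_batch

__all__ = [
    "SerialStats",
    "acf1",
    "batch_acf1",
    "run_simulation_study",
    "optimal_beta_table",
    "performance_report",
]

#: Fraction-of-correction grid of the optimality study: 0.06 .. 0.96 in
#: steps of 0.06 (16 values).
DEFAULT_BETA_GRID = tuple(np.round(np.arange(1, 17) * 0.06, 2))
#: Execution-noise SDs of the study (s).
DEFAULT_SIGMA_M_GRID = (0.022, 0.05, 0.1, 0.2)


@dataclass
class SerialStats:
    """Lag-1 autocorrelation with a null band and a classification."""

    acf1: float
    n: int
    ci_low: float
    ci_high: float
    classification: str


def _acf1_value(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    denom = float(np.sum(d * d))
    if denom == 0:
        raise ValueError("series has zero variance; acf(1) undefined")
    return float(np.sum(d[:-1] * d[1:]) / denom)


def acf1(series: np.ndarray) -> SerialStats:
    """Sample lag-1 autocorrelation with the 95% null band ±1.96/sqrt(n).

    Uses the conventional biased (divide-by-n) covariance normalization.
    Classification: ``undercorrection`` if acf(1) exceeds the upper bound,
    ``overcorrection`` below the lower bound, else ``near-optimal``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 trials for acf(1)")
    r1 = _acf1_value(x)
    bound = 1.96 / np.sqrt(n)
    if r1 > bound:
        cls = "undercorrection"
    elif r1 < -bound:
        cls = "overcorrection"
    else:
        cls = "near-optimal"
    return SerialStats(r1, n, -bound, bound, cls)


def batch_acf1(series: np.ndarray) -> np.ndarray:
    """Row-wise lag-1 autocorrelation of a (reps, trials) array."""
    x = np.asarray(series, dtype=float)
    d = x - x.mean(axis=1, keepdims=True)
    return np.sum(d[:, :-1] * d[:, 1:], axis=1) / np.sum(d * d, axis=1)


def run_simulation_study(
    beta_grid=DEFAULT_BETA_GRID,
    sigma_m_grid=DEFAULT_SIGMA_M_GRID,
    config: SimulationConfig | None = None,
    n_reps: int = 1000,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int | None = None,
    fisher_average: bool = False,
    windowed_gain: bool = False,
) -> pd.DataFrame:
    """Simulate every (beta, sigma_m) pair and summarize the outcome.

    For each combination, ``n_reps`` replicate series of ``config.n_trials``
    trials are generated (mean process variance over the speed list, the
    default), the first ``burn_in`` trials are discarded, and the mean
    error variance and mean acf(1) of errors and onsets are recorded
    together with two theoretical gains for the noise pair: the one-step
    ``gain`` V_t/(V_t + sigma_m^2) and the ``steady_gain`` solving the
    scalar Riccati equation. ``fisher_average`` averages acf(1) across
    replicates on the Fisher-z scale instead of the raw scale; both are
    reported (columns ``acf1_e``/``acf1_onset`` switch, the raw means are
    always in ``acf1_e_raw``/``acf1_onset_raw``). ``windowed_gain`` adds a
    ``gain_windowed`` column computed from the mean 4-trial moving-window
    variance of the simulated onsets, the estimator the filter uses on
    behavioral series.
    """
    beta_grid = tuple(beta_grid)
    sigma_m_grid = tuple(sigma_m_grid)
    if not beta_grid or not sigma_m_grid:
        raise ValueError("parameter grids must be non-empty")
    if config is None:
        config = SimulationConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    for sigma_m, ss in zip(sigma_m_grid, root.spawn(len(sigma_m_grid))):
        for beta, ss_b in zip(beta_grid, ss.spawn(len(beta_grid))):
            rng = np.random.default_rng(ss_b)
            cfg = config.replace(beta=beta, sigma_m=sigma_m, vt_mode="mean")
            _, onset, error = simulate_batch(cfg, n_reps=n_reps, rng=rng)
            onset = onset[:, burn_in:]
            error = error[:, burn_in:]
            r_e = batch_acf1(error)
            r_on = batch_acf1(onset)
            vt = cfg.mean_vt
            row = {
                "beta": beta,
                "sigma_m": sigma_m,
                "var_e": float(np.mean(np.var(error, axis=1, ddof=1))),
                "acf1_e_raw": float(np.mean(r_e)),
                "acf1_onset_raw": float(np.mean(r_on)),
                "acf1_e_z": float(np.tanh(np.mean(np.arctanh(np.clip(r_e, -0.999999, 0.999999))))),
                "acf1_onset_z": float(np.tanh(np.mean(np.arctanh(np.clip(r_on, -0.999999, 0.999999))))),
                "gain": static_gain(vt, sigma_m ** 2),
                "steady_gain": steady_state_gain(vt, sigma_m ** 2),
            }
            if windowed_gain:
                w = 4
                sliding = np.lib.stride_tricks.sliding_window_view(onset, w, axis=1)
                vt_win = float(np.mean(np.var(sliding, axis=2, ddof=1)))
                row["gain_windowed"] = static_gain(vt_win, sigma_m ** 2)
            rows.append(row)
    df = pd.DataFrame(rows)
    which = "z" if fisher_average else "raw"
    df["acf1_e"] = df[f"acf1_e_{which}"]
    df["acf1_onset"] = df[f"acf1_onset_{which}"]
    df.attrs.update(
        beta_grid=beta_grid,
        sigma_m_grid=sigma_m_grid,
        n_reps=n_reps,
        n_trials=config.n_trials,
        burn_in=burn_in,
        seed=seed,
        acf_normalization="biased (divide by n)",
    )
    return df


def optimal_beta_table(study: pd.DataFrame) -> pd.DataFrame:
    """Per-sigma_m argmin of the error variance over the beta grid.

    Returns one row per sigma_m with the variance-minimizing beta, the
    acf(1) of the errors at that beta, and the two theoretical gains.
    """
    rows = []
    for sigma_m, grp in study.groupby("sigma_m", sort=True):
        i = grp["var_e"].idxmin()
        rows.append(
            {
                "sigma_m": sigma_m,
                "beta_opt": grp.loc[i, "beta"],
                "var_e_min": grp.loc[i, "var_e"],
                "acf1_e_at_opt": grp.loc[i, "acf1_e"],
                "gain": grp.loc[i, "gain"],
                "steady_gain": grp.loc[i, "steady_gain"],
            }
        )
    return pd.DataFrame(rows)


def performance_report(
    table: pd.DataFrame, n_blocks: int = 4, hit_threshold: float = 0.020
) -> pd.DataFrame:
    """Fraction of hits (|error| < 20 ms) per sequential block of the session.

    Trials of each subject x condition series are split into ``n_blocks``
    equal consecutive blocks; existing ``hit`` flags are used when present,
    otherwise recomputed from ``error_s``.
    """
    if table.empty:
        raise ValueError("empty trial table")
    df = table.copy()
    if "hit" not in df.columns:
        df["hit"] = (df["error_s"].abs() < hit_threshold).astype(int)
    keys = [k for k in ("subject", "condition") if k in df.columns]

    def _blocks(g: pd.DataFrame) -> pd.Series:
        edges = np.array_split(np.arange(len(g)), n_blocks)
        return pd.Series(
            {b + 1: g["hit"].to_numpy()[ix].mean() for b, ix in enumerate(edges)}
        )

    if keys:
        out = df.groupby(keys, sort=True).apply(_blocks, include_groups=False)
        out = out.reset_index().melt(
            id_vars=keys, var_name="block", value_name="hit_fraction"
        )
    else:
        out = _blocks(df).rename_axis("block").reset_index(name="hit_fraction")
    return out.sort_values(keys + ["block"]).reset_index(drop=True) if keys else out
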