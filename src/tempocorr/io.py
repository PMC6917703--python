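"""Trial-table I/O with validation, and metadata sidecars.

The tabular interchange format is CSV with a fixed header; every output
file gets a JSON sidecar (same path + ``.meta.json``) holding the
parameters and seed needed to regenerate it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "TrialTableError",
    "MissingColumnError",
    "NonMonotoneTrialsError",
    "UnitSuspicionWarning",
    "read_trial_table",
    "write_with_sidecar",
    "read_sidecar",
]

REQUIRED_COLUMNS = (
    "subject",
    "condition",
    "trial",
    "speed",
    "onset_s",
    "movement_time_s",
    "error_s",
)
OPTIONAL_COLUMNS = ("n_peaks", "hit", "tau_s", "session")

#: Plausible range for an action onset in seconds; values outside trigger a
#: unit-suspicion warning (e.g. onsets near 500 suggest milliseconds).
ONSET_RANGE_S = (0.0, 5.0)


class TrialTableError(ValueError):
    """Base class for trial-table validation failures."""


class MissingColumnError(TrialTableError):
    def __init__(self, column: str):
        self.column = column
        super().__init__(f"trial table is missing required column {column!r}")


class NonMonotoneTrialsError(TrialTableError):
    def __init__(self, subject, condition):
        super().__init__(
            f"trial indices are not strictly increasing for subject "
            f"{subject!r}, condition {condition!r}"
        )


class UnitSuspicionWarning(UserWarning):
    """Onset values look like they are not in seconds."""


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Checks the required header, strictly increasing trial indices within
    each subject x condition (x session) series, and an onset range
    heuristic for second-vs-millisecond confusion. Unit suspicion is a
    warning, not an error: the table loads, flagged with
    ``df.attrs["unit_suspicious"] = True``.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(col)
    keys = ["subject", "condition"] + (["session"] if "session" in df.columns else [])
    for key, g in df.groupby(keys, sort=False):
        trials = g["trial"].to_numpy()
        if not (trials[1:] > trials[:-1]).all():
            raise NonMonotoneTrialsError(g["subject"].iloc[0], g["condition"].iloc[0])
    lo, hi = ONSET_RANGE_S
    suspicious = bool(
        ((df["onset_s"] <= lo) | (df["onset_s"] >= hi)).mean() > 0.5
    )
    df.attrs["unit_suspicious"] = suspicious
    if suspicious:
        warnings.warn(
            "more than half of the onset values fall outside the plausible "
            f"range {ONSET_RANGE_S} s; the column may be in milliseconds",
            UnitSuspicionWarning,
            stacklevel=2,
        )
    return df


def write_with_sidecar(df: pd.DataFrame, path, metadata: dict) -> Path:
    """Write a CSV and a JSON metadata sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str))
    return path


def read_sidecar(path) -> dict:
    path = Path(path)
    return json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
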