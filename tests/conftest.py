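import numpy as np
import pandas as pd
import pytest

from tempocorr import SimulationConfig, simulate_series

#: mean planning variance with the standard spatial/timing SDs and speeds
MEAN_VT = np.mean([(1.0 / v) ** 2 + 0.05 ** 2 for v in (20.0, 25.0, 30.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def arm_like_table(rng):
    """Small multi-subject arm-like trial table with movement-time noise."""
    frames = []
    for subj in range(1, 6):
        mt = rng.normal(0.45, 0.05, 120)
        cfg = SimulationConfig(
            beta=0.4, sigma_m=0.05, sigma_x=0.0, sigma_t=0.0,
            n_trials=120, target_time=0.8, movement_time=mt,
        )
        df = simulate_series(cfg, rng=rng).to_frame()
        df.insert(0, "condition", "arm")
        df.insert(0, "subject", subj)
        df["n_peaks"] = 1 + (rng.random(120) < 0.3).astype(int)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
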