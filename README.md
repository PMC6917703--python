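# tempocorr

Trial-to-trial temporal-correction analysis for interception timing tasks
(reaching at a moving target, interceptive saccades, timed button presses).

## The problem

When people repeatedly try to intercept a moving target, the timing of each
attempt is shaped by two error signals: the **final temporal error** `e`
(how early or late the effector crossed the target's path) and the
**prediction error** `Ts − τ` (how far the actual movement onset `Ts`
landed from the planned onset `τ`). How much of each error is fed into the
next trial's plan, and how that depends on movement duration, is the
question this package quantifies.

The core generative model is a corrected random walk of the planned onset:

```
Ts_i      = τ_i + r,               r ~ N(0, σ_m²)        execution noise
e_i       = T_T − (Ts_i + Tm_i)                          final error (+ = early)
τ_{i+1}   = τ_i + β·e_i + q,       q ~ N(0, V_t)         correction + planning drift
V_t       = (σ_x / v)² + σ_t²                            planning-noise variance
```

with `T_T` the target's time-to-contact, `Tm` the movement time, `v` the
target speed, and `β` the fraction of the previous error corrected for.
Three diagnostic tools sit on top of it:

- **Lag-1 autocorrelation of the errors.** No correction (β = 0) lets
  planning noise accumulate: acf(1) > 0. Over-correction (β = 1)
  over-compensates execution noise: acf(1) < 0. The variance-minimizing β
  leaves acf(1) ≈ 0, so the autocorrelation classifies a series as
  under-correcting, over-correcting or near-optimal.
- **A scalar Kalman filter** that estimates the latent planned onset from
  the observed onsets, with the execution-noise variance σ_m² as the only
  free parameter and the process variance taken from a 4-trial moving
  window. Its gain `K_i = P_i/(P_i + σ_m²)` is the fraction of the
  prediction error carried into the next plan.
- **A coupled time-course model** of how the two weights trade off with
  movement time `Tm`: the feedback weight is zero up to a sensorimotor
  delay δ_sm and rises linearly afterwards (β_t = b₁·Tm + b₀, pinned to
  (1−c)² at Tm = 550 ms), while the prediction weight decays as
  `K_t = √(c² − a·β_t²)`; (δ_sm, a, c) are the free parameters.

A kinematics module turns raw position traces into movement onsets
(zero-phase 4th-order Butterworth at 8 Hz, three-point central-difference
speed, backward-iterative 10%-of-peak onset detection), velocity-peak
counts (markers of online corrections), and applies the saccade validity
rule (discard if amplitude gain < 0.5 or duration > 100 ms).

## Worked example

```python
import numpy as np
from tempocorr import (SimulationConfig, simulate_series, acf1,
                       fit_measurement_noise, static_gain,
                       mean_planning_variance)

vt = mean_planning_variance(1.0, 0.05, (20, 25, 30))
print(f"mean planning variance V_t = {vt:.4f} s^2")
print(f"gain at sigma_m = 0.1 s:     {static_gain(vt, 0.1**2):.3f}")

cfg = SimulationConfig(beta=0.3, sigma_m=0.1, n_trials=360, seed=7)
series = simulate_series(cfg)
stats = acf1(series.error[20:])
print(f"acf(1) of the final errors = {stats.acf1:+.3f} ({stats.classification})")

fit = fit_measurement_noise(series.onset)
print(f"fitted execution-noise SD  = {fit.sigma_m:.3f} s")
print(f"mean Kalman gain           = {fit.mean_gain:.3f}")
```

prints

```
mean planning variance V_t = 0.0042 s^2
gain at sigma_m = 0.1 s:     0.298
acf(1) of the final errors = +0.324 (undercorrection)
fitted execution-noise SD  = 0.078 s
mean Kalman gain           = 0.698
```

Reading it: with the standard spatial (1 cm) and timing (0.05 s)
uncertainties and the three interleaved target speeds, planning noise has
variance 0.0042 s²; paired with 100 ms execution noise the one-step Kalman
gain is 0.30. A series simulated at β = 0.3 under-corrects (the
variance-minimizing fraction for this noise pair is ≈ 0.47, the
steady-state gain), which the positive error autocorrelation picks up; the
filter fitted to the observed onsets recovers an execution-noise SD near
the simulated 0.1 s.

The same analyses run from the shell:

```
tempocorr simulate --condition arm --n-subjects 8 --seed 1 --out run/
tempocorr acf         --input run/trials.csv --out run/
tempocorr kalman-fit  --input run/trials.csv --out run/
tempocorr report --seed 1 --out run/        # full pipeline + JSON report
```

Every output CSV gets a `.meta.json` sidecar with the parameters and seed
that produced it; a fixed seed makes a run byte-identical.

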