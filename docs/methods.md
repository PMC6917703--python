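# Methods

## Generative model

One trial series is a corrected random walk of the planned action onset
τ (seconds, relative to target motion onset):

    Ts_i    = τ_i + r,            r ~ N(0, σ_m²)
    e_i     = T_T − (Ts_i + Tm_i)
    τ_{i+1} = τ_i + β e_i + q,    q ~ N(0, V_t)

Sign convention: `e > 0` means the effector was **early** at the
interception zone. A positive error therefore pushes the next planned
onset later — the `+β e` term is corrective and the process is stationary
for β ∈ (0, 2). (Writing the update with a minus sign against this error
convention would make the dynamics divergent; the package fixes the
convention once, here, and all tables store `error_s` early-positive.)

The planning-noise variance has a velocity-dependent and a timing
component, `V_t = (σ_x/v)² + σ_t²`. Defaults: σ_x = 1 cm, σ_t = 0.05 s,
speeds 20/25/30 cm/s interleaved uniformly at random per trial, giving a
mean V_t of 0.0042 s². Two modes exist for drawing the planning noise:
per-trial speed-specific variance (`vt_mode="per_trial"`, the default for
experiment emulation) and the mean variance throughout (`"mean"`, the
default for the optimality study, where a single noise level per condition
keeps the β grid comparable).

τ₀ starts at the error-free onset `T_T − mean(Tm)` (overridable); any
start-up transient decays under β > 0 and the first 20 trials are
discarded before summary statistics. In pure simulations `T_T` and `Tm`
are zero; experiment emulation sets them per condition (time-to-contact
0.8 s for arm/button, 0.6 s for eye; movement time constant 330 ms for the
button-released cursor, ~52 ms for saccades, subject-specific means in
0.3–0.6 s with trial-to-trial SD 0.02 s for arm). A hit is |e| < 20 ms.
Randomness comes from one root seed with per-subject/per-replicate child
streams (`numpy SeedSequence.spawn`), recorded in output sidecars.

What the generator does **not** emulate: saccadic suppression, perceptual
noise on the displayed feedback, KR vs KP feedback formats, spatial
(2-D) errors, or learning of β itself. Conditions differ only through
parameters, so passing tests show the estimators behave correctly on data
from this model class — not that real behavior follows the model.

## Optimality of corrections (simulation study)

For each (β, σ_m) on the default grid (β = 0.06…0.96 in steps of 0.06;
σ_m = 0.022, 0.05, 0.1, 0.2 s), replicate series of 360 trials are
simulated and the error variance and lag-1 autocorrelations recorded. The
acf estimator divides by n (the conventional biased normalization; the
Fisher-z-averaged replicate mean is also reported). The study exposes two
theoretical gains per noise pair:

- the one-step gain `K = V_t/(V_t + σ_m²)`;
- the steady-state gain solving the scalar Riccati fixed point
  `K² σ_m² = V_t (1 − K)`.

Analytically — and the tests verify this — the variance-minimizing β
equals the **steady-state** gain, and at that β the lag-1 autocorrelation
of the errors is exactly zero (the stationary variance of τ there
satisfies `(1−β)·var(τ) = β·σ_m²`). The one-step gain approximates the
variance minimizer only when V_t ≫ σ_m² (0.90 vs 0.91 at σ_m = 0.022) and
departs substantially at high execution noise (0.30 vs 0.47 at σ_m = 0.1;
0.09 vs 0.28 at σ_m = 0.2). One acceptance test asserts the one-step
identification and is expected to fail at the high-noise levels; the
module tests assert the steady-state property.

Default study size: 200 replicates per grid point (16 × 4 grid), which
puts the Monte-Carlo SE of the per-point error variance near 0.5% —
enough to resolve the U-shape and the argmin to about one grid step.

## Kalman filter and the execution-noise fit

Scalar filter per trial: prior `P_i = P̂_{i−1} + V_t,i`, gain
`K_i = P_i/(P_i + σ_m²)`, posterior `τ̂_i = τ_i + K_i (Ts_i − τ_i)`,
`P̂_i = (1 − K_i) P_i`; the posterior is the next trial's prior planned
onset, and `Ts_i − τ_i` is the prediction error. Initialization: τ₀ = the
first observation, P₀ = the mean process variance (so the first-trial gain
is close to the one-step gain); the first 5 trials are excluded from the
fit objective and the mean gain. Gains are bounded in [0, 1] and the
posterior variance never exceeds the prior — both assertable on every fit.

Per-trial process variance: the sample variance (n−1) of the 4 observed
onsets trailing the current trial (trials i−4…i−1), so the prior never
uses the observation it is scored against; the first trials receive the
first computable value. This estimator is upward-biased as an estimate of
V_t — a window of observed onsets contains σ_m² itself plus local state
wander — which matters below.

**Identification of σ_m².** The naive least-squares criterion
Σ(Ts_i − τ_i)² cannot identify the parameter: on any mean-reverting
(well-corrected) series it is monotone in σ_m, because shrinking the gain
turns the prior into a running mean, the best mean-square one-step
predictor of a stationary series. The fit therefore applies least squares
to the **squared** prediction errors against their filter-implied
innovation variances, minimizing Σ(pe_i² − (P_i + σ_m²))² over
σ_m ∈ [10⁻⁴, 1] s by bounded scalar search (three overlapping brackets,
xatol 10⁻¹⁰). On a correctly specified random-walk-plus-noise series this
estimating equation is consistent, and a pure random walk fits to a
near-zero σ_m. The naive criterion remains available
(`objective="sse"`).

Known bias: with the windowed V̂_t the fitted noise *ratio* is roughly
scale-invariant, so while the median fitted σ_m lands within ~±30% of
truth at moderate noise (0.05–0.1 s), the fitted mean gain does **not**
decrease with the true σ_m (it sits near 0.67 across levels). Supplying a
known process variance (`vt=`) restores the gain ordering at the cost of
inflating the fitted σ_m at low noise levels. Both paths are exposed; the
per-subject "gain" is reported both as the trial-average K_i and as the
steady-state value at the mean V̂_t, since either reading is defensible.

## Lag-1 dependency and the slope → β calibration

Per subject, OLS of the current onset on the previous final error (plus
the previous velocity-peak count when available), pooled across subjects
by inverse-variance weighting; a full mixed-effects model is deliberately
not used — the pooled per-subject estimand approximates its fixed effect.
Fast/slow stratification splits each subject's trials at their median
movement time. Pairs straddling session boundaries are dropped and
counted.

The raw slope is a *biased* estimator of β: under the generative dynamics
the population slope is `β − var(τ)/var(e)`, which equals exactly β/2 in
the drift-free regime (V_t = 0) regardless of how the noise splits between
execution and movement time. The package therefore estimates a calibration
line by simulating multi-subject series over a β grid (drift-free, with
movement-time variability SD 0.05 s), regressing β on the pooled slopes,
and inverting; the line comes out as β ≈ 2·slope through the origin and is
monotone by construction of the regime. Correction-fraction recovery is
always reported through this calibration. The drift-free calibration
regime is a deliberate choice: with V_t > 0 the β = 0 endpoint is a
nonstationary random walk and no line through the origin exists.

## Coupled time-course model

Free parameters (δ_sm, a, c) with `β_t = 0` for Tm ≤ δ_sm, else linear
with the two constraints `β_t(δ_sm) = 0` and `β_t(0.550 s) = (1−c)²`
(which eliminate b₀, b₁), and `K_t = √(c² − a β_t²)` (clipped at zero
under the root when a candidate parameter set would make it imaginary,
which penalizes such candidates). δ_sm is fitted by grid search — coarse
10 ms pass over 0.1–0.5 s, then a 1 ms refinement around the coarse
minimum, nested least squares in (a, c) warm-started between grid points —
because the piecewise boundary makes the objective non-smooth in δ_sm. K
and β point sets enter the residual with equal weight; the Kalman-gain
contribution is scaled by its maximum admissible value (division by the
fitted maximum; min–max scaling across subjects is available as an
option). The fit is exact (residual ~0) on noiseless self-generated points
for any admissible parameter set, and under point noise of SD 0.05 the
delay is recovered to well within ±30 ms in the median.

## Kinematic preprocessing

Positions are filtered with a zero-phase (forward–backward) 4th-order
Butterworth at 8 Hz (second-order-sections, even reflective padding; the
bidirectional pass squares the magnitude response, and the tests check it
against the exact bilinear-transform formula). Speed is the absolute
three-point central difference (one-sided at the endpoints). Movement
onset uses the backward-iterative rule: find the first sample at ≥10% of
peak speed, then walk backwards, refreshing the tolerance to 10% of each
visited sample, and stop at the first earlier sample below the current
tolerance (sample 0 if the walk exhausts — a conservative boundary
choice). Velocity peaks are local maxima with prominence ≥5% of peak speed
(a noise-robustness default, exposed in the config) between onset and the
target-line crossing; a movement whose only maximum falls after the
crossing counts zero peaks. Saccades are kept unless amplitude gain < 0.5
or duration > 100 ms (strict inequalities); the online trigger threshold
(74 deg/s) and offline detection thresholds (30 deg/s, 8000 deg/s²) are
recorded as constants but only the validity rule is applied to tables.

Limitation: the backward relative-drop rule is exact on clean profiles
(the speed of a bell-shaped movement rises quadratically at the onset
corner, so the 10% relative drop fires within ~1.5 samples), but once the
walk enters a noisy or filter-rippled baseline the stop condition fires
only at near-zero dips, which occur at random sign-change nodes: on
synthetic flat-baseline traces the detector is then systematically early
by roughly 0.1–0.2 s at any noise level. The tests pin the algorithm to a
brute-force oracle, verify one-sample accuracy on the clean chain, and
assert the early-never-late property of the noisy filtered chain.

## Pipeline and I/O

CSV is the only tabular format (columns `subject, condition, trial, speed,
onset_s, movement_time_s, error_s, n_peaks, hit`, plus the ground-truth
`tau_s` for simulated tables). Validation raises named errors for missing
columns and non-monotone trial indices; onsets mostly outside (0, 5) s
raise a unit-suspicion warning (milliseconds?) but load, flagged. Every
output carries a JSON sidecar with the full config and seed, sufficient to
regenerate it byte-identically; stage timings and row counts go to the
log, not into files, so reruns stay deterministic.

## Problem sizes

Defaults used by the test suite and acceptance checks: the optimality grid
at 16 × 4 × 200 replicates × 360 trials; execution-noise recovery at 200
replicate fits per noise level; correction-fraction recovery at 15
subjects × 360 trials per β with a 10-point calibration grid; coupled-
model noise recovery at 500 replicate fits. These sizes put Monte-Carlo
error comfortably below the tolerances asserted while keeping a full run
in the low minutes on one core.
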