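# Methods

`intflex` studies how intrinsic neural timescales (INT) change between
behavioral states, and what network mechanism can produce that change. It
has two halves: an empirical-style pipeline (windowed timescale estimation
from multichannel recordings, behavioral segmentation, statistics, state
decoding) and a connectome-coupled firing-rate model. A synthetic-data
module generates every input with known ground truth, so all claims the
test suite makes are about recovery of known quantities.

## Timescale estimation

For a demeaned window `x` of length `N`, the autocorrelation function uses
the biased normalization

    r_l = sum_{t=1..N-l} (x_t - x̄)(x_{t+l} - x̄) / sum_{t=1..N} (x_t - x̄)²,

so `r_0 = 1` exactly. It is evaluated by FFT; the test suite checks
equality with the literal double sum to 1e-10.

Two summaries are derived per window and channel:

* **tau** — least-squares fit of `exp(-l/tau)` to `r_l`. The fit spans
  lags 1 through the first lag at which the ACF drops below 1/e. The lag-0
  point is identically 1 and carries no information. The tail is excluded
  deliberately: the finite-window ACF estimate carries a negative bias of
  roughly `-2·tau_samples/N` at every lag ≥ 1 (a consequence of
  subtracting the within-window mean), and because `r_0` is pinned at 1,
  fitting the full lag range reads that offset as extra-fast decay. On
  Ornstein–Uhlenbeck (OU) ground truth with 10-s windows at 20 Hz, a
  full-range fit under-recovers tau by ~35% at tau = 0.5 s; the truncated
  fit keeps the median bias within ~22% for tau ≤ 0.5 s and preserves rank
  order across tau values, which is what the downstream comparisons use.
  Windows whose ACF never reaches 1/e within the computed lags (half the
  window length) cannot pin down tau; they are flagged non-converged and
  excluded downstream. The minimizer is a log-spaced grid scan polished by
  safeguarded Newton steps; it recovers a noiseless exponential to machine
  precision.
* **ACW-0** — the first zero crossing of the ACF, linearly interpolated
  between the bracketing lags; undefined (NaN, window excluded) when the
  ACF stays positive.

Windowing is non-overlapping, 10 s by default; an incomplete trailing
window is dropped. Band powers integrate the periodogram with the
trapezoid rule between band edges. In the default band table "theta" is
1–4 Hz and "delta" 4–7 Hz — deliberately the reverse of the common
convention, to stay interoperable with analyses that label the ranges
this way. The names are configurable; the code does not silently
"correct" them.

## Behavioral segmentation

Wheel velocity is binarized at a configurable threshold (default 0.25
velocity units — the threshold used in the source data is unreported) with
morphological smoothing: sub-second rest gaps are filled, then sub-second
run bouts removed. Five classes of 10-s windows are cut around each
running bout, each gated by duration preconditions on the bout and its
flanking rest (onset; locomotion = middle 10 s of a ≥20-s bout with ≥60-s
pre-rest; offset; initial rest; sustained rest = 10 s starting 40 s after
bout end). One bout may emit several classes, and the offset and
initial-rest windows of the same bout overlap by construction; both are
emitted. The "middle 10 s" window is centered on the bout midpoint,
rounded to the sample grid.

## Statistics

Percent change is `((task - rest)/rest)·100` per channel on
across-window means; it is undefined (excluded) for non-positive rest
values. Group comparisons use Wilcoxon tests — signed-rank for paired
data (zero differences dropped), rank-sum otherwise — with a
continuity-corrected normal z at n ≥ 10 and exact enumeration below. The
default effect size is the rank-biserial correlation (paired:
`(W⁺ - W⁻)/(W⁺ + W⁻)`; unpaired: `2U/(n₁n₂) - 1`), bounded in [-1, 1]; a
`z/sqrt(n_smaller)` variant is available, which is unbounded and can
exceed 1. Spearman correlations report p from the t approximation on
`n - 2` degrees of freedom. Outlier removal keeps values within 3 scaled
(×1.4826) median absolute deviations of the median. Multiple comparisons
use Holm's step-down adjustment. The Clogg test compares one predictor's
coefficient between a reduced and a covariate-augmented model fitted on
the same data; because the models are nested, the variance of the
coefficient difference is the difference of the squared standard errors,
and a non-positive difference raises an error rather than silently
producing a z.

## State classification

Windows × channel-tau tables are classified with an RBF-kernel SVM or
multinomial logistic regression inside nested cross-validation (10 outer,
10 inner stratified folds). Regularization and kernel scale are drawn
log-uniformly (30 candidates per inner search by default) and scored only
on inner folds of the outer-training split; feature standardization is
fitted on training folds inside the pipeline, so outer test folds never
influence tuning. Outer folds partition the data, so the aggregated
confusion matrix counts every window exactly once. Per-class one-vs-rest
ROC curves are interpolated as right-continuous steps onto a 101-point
false-positive-rate grid, then averaged with an across-fold SD band; the
AUC of the mean curve is reported. Everything is seeded and
bit-reproducible.

## Firing-rate model

Each of N regions obeys

    tau_i dx_i/dt = -x_i + f(Σ_j W_ij x_j + b + s + I),   f(u) = 1/(1+e^{-ru}),

with b = -3, r = 0.5, unit-variance Gaussian noise s drawn once per region
per integration step, and external input I (0 at rest, 1 stimulated). The
coupling matrix's off-diagonal is scaled by a single scalar so the mean
off-diagonal row sum is 2; the diagonal is the recurrent strength (default
1). Integration is explicit midpoint (RK2) at dt = 0.01 s for 300 s with
the first 100 s discarded; the noise vector is held fixed across both
stages of a step so the deterministic RK2 update stays well-defined, and
no √dt scaling is applied (the noise is read as a per-step input, not an
SDE increment — a 10× larger √dt-scaled noise drives the rates toward the
sigmoid's midpoint and erases the rest–stimulation timescale effect).
Initial rates are Uniform(0,1); the discard makes them immaterial, which a
test asserts. Rates stay inside (0,1) throughout.

**Node time constant.** We use tau_i = 30 ms, the scale of
membrane/synaptic integration conventionally used in firing-rate models,
exposed in `ModelParams`. The choice matters for measurement, not just
dynamics: the windowed-tau estimator's sampling noise scales as
`sqrt(2·tau/T_window)`, so with tau on the order of seconds a 10-s window
contains too few correlation times for the rest-vs-stimulation comparison
to resolve the few-percent tau change at any pooled sample size;
resolving it requires tau in the tens of milliseconds. At 30 ms the model
produces the full effect-size ladder: negligible effect without
recurrence, growth to a maximum near W_ii = 2, collapse at 3, and sign
reversal at 3.5–4 as strong self-excitation saturates the stimulated
rates.

**Rate clamping.** To control for firing-rate differences, a per-region
input I_i relaxes (time constant tau_I = 0.05 s) toward the steady-state
solution

    Ĩ_i = logit(x̄)/r - Σ_{j≠i} W_ij x_j - W_ii x̄ - b,

which makes the transfer function return the target rate x̄ exactly
(machine-precision identity, tested). Targets are 0.1 (rest) and 0.6
(stimulated). Noise is kept in the rate equation so clamped trajectories
still fluctuate and windowed timescales remain defined; the sigmoid's
curvature then biases the achieved mean rate upward by ~0.01 at the 0.1
target, within the 0.02 tolerance the analyses use.

**Edge shuffling** permutes a chosen fraction of off-diagonal entries
among their positions, preserving the weight multiset and the diagonal — a
topology null that leaves recurrent strengths intact.

**Lyapunov spectra** come from Benettin-style QR re-orthonormalization of
a full deviation basis propagated through the linearized flow along the
noise-free trajectory, after a 20-s attractor warmup. Trajectory and
tangent use classical RK4 — the spectrum describes the continuous-time
flow, and the lower-order simulation map would contribute a visible
truncation bias at dt/tau = 1/3. The first 20% of QR steps are excluded
from the exponent average so the random initial basis can align with the
covariant directions; with clustered spectra the per-exponent estimates
still converge only ~1/T, so two random bases agree to finite-time
precision (a few percent of 1/tau), not machine precision. In every swept
configuration (W_ii 0–4, rest and stimulated) all exponents are negative:
the model is not chaotic, so chaos does not confound the timescale
comparisons.

**Sweeps.** For each recurrent strength, independent rest and stimulation
runs are reduced to one tau (and ACW-0) per region per run (mean over its
10-s windows, non-converged windows dropped); the two conditions are
pooled across regions and simulations and compared with the unpaired rank
test. The model analog of the rest-variability analysis correlates each
region's across-window rest tau SD with its rest-to-stimulation percent
change (Spearman), which comes out reliably negative.

## Synthetic data

* **OU recordings** use the exact AR(1) discretization
  `x[t+1] = φ x[t] + ε`, `φ = exp(-1/(fs·tau))`, innovation variance
  `σ²(1-φ²)` — lag-1 autocorrelation and stationary SD are exact, with no
  Euler discretization drift. State-dependent recordings switch φ at state
  boundaries while keeping the trajectory continuous, and carry
  sample-exact labels. What this emulates: the timescale structure of the
  data. What it does not: calcium indicator dynamics, hemodynamic
  cross-talk, volume conduction, 1/f backgrounds, oscillations. Passing
  recovery tests therefore demonstrate estimator correctness, not
  robustness to those real-data features.
* **Velocity traces** are rest/run/rest epochs of Gaussian noise around 0
  or around the run speed — the simplest trace exercising every duration
  rule of the segmentation heuristic.
* **Connectomes** are dense symmetric lognormal(0, 1) weight matrices
  (zero diagonal), optionally sparsified. This matches an averaged DTI
  matrix in nonnegativity, heavy-tailed weights and density, but not in
  its spatial embedding or hub topology; the distribution is a stand-in,
  and the model results reported here are for this synthetic ensemble.

All generators take explicit integer seeds and never touch global RNG
state.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale conditions: estimator recovery uses
200 10-s windows per ground-truth tau at 20 Hz; the recurrent sweep uses a
360-region synthetic connectome, 10 simulations per strength over
W_ii ∈ {0, 0.5, 1, 2, 4}; the clamped-rate checks use 4 simulations per
W_ii ∈ {0, 1, 2, 3} per target; Lyapunov sweeps run a 64-region connectome
for 5000 steps per configuration; classification sanity checks use 400–500
windows with 10×10 nested folds and 10 search candidates per inner loop.

## Known limitations

* The tau estimator's residual negative bias grows with tau/window ratio;
  comparisons between conditions are unaffected (both conditions share the
  bias), but absolute tau values from 10-s windows should be read with
  that in mind.
* The rank-biserial effect size is bounded in [-1, 1] by construction;
  unbounded "biserial r" values reported elsewhere (e.g. > 1) cannot be
  reproduced by it and are matched only qualitatively.
* The model's connectome is synthetic; quantitative effect sizes depend on
  the weight ensemble, and only the qualitative structure (effect ordering
  and reversal across recurrent strengths, negative variability–change
  coupling) should be compared across connectomes.
* The excitatory–inhibitory two-population variant, raw-signal
  preprocessing (hemodynamic correction, ICA artifact rejection), and
  mixed-effects models are out of scope.
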