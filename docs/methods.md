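# Methods

## Model families and time conventions

All five families are linear time-invariant discrete-time systems in the
stride index, `X(n+1) = A X(n) + B u(n)`, `y(n+1) = C X(n+1) + D u(n+1)`.
An input schedule of length N lists `u(0) … u(N−1)`; observations are
reported for strides 1…N, and the direct-feedthrough input of the final
stride, `u(N)`, is held at the last schedule entry. Simulations start from
`X(0) = x_init`, default zero: baseline referencing (below) sets the
unperturbed response to ≈ 0, so rest is the natural origin. One consequence
of pairing `y(n)` with `u(n)` while the protocol builder lays out its blocks
by array position is that the feedthrough term leads the block labels by one
sample at block edges; this is a fixed convention applied identically in
generation and fitting, so it cancels everywhere the two meet.

`simulate_native` iterates each family's original update equations — with
the explicit error signal `e(n) = y(n) − x(n)` where the family uses one —
and serves as an independent oracle for the canonical matrices:

- single-state: `x(n+1) = a x(n) + b e(n)` collapses to `a′ = a − b + bc`,
  `b′ = bd`. Both parameterizations are accepted; the canonical 4-parameter
  form is the fitted one.
- UDL: `x(n+1) = au x(n) + bu y(n) + (1 − au − bu) x0` with `x0 = 0` (the
  data are referenced to zero), giving the scalar system
  `A = au + bu`, `B = bu du`.
- fast/slow: two error-driven states with `e(n) = d u(n)` after
  substitution; `A = diag(af, as)`, `B = d [bf, bs]ᵀ`, `C = [1, 1]`.
- modified UDL: the reference state obeys `x0(n+1) = cmu x0(n) + (1 − cmu) y(n)`,
  giving `A′ = [[cmu, 1 − cmu], [1 − amu − bmu, amu + bmu]]`,
  `B = dmu [1 − cmu, bmu]ᵀ`, `C = [0, 1]`.
- two-state: the canonical form *is* the model; all nine entries free.

## Stability, after-effects, and the modified-UDL structure

"Stable" means no eigenvalue of `A` of magnitude above `1 + 1e−9`.
Marginal stability must be admitted because the modified-UDL `A′` has rows
summing to one and therefore always carries an eigenvalue of exactly 1; the
free eigenvalue is `amu + bmu + cmu − 1`. The left eigenvector of the unit
mode, `w = [1 − amu − bmu, 1 − cmu]`, yields a conservation law under
washout (`u = 0`): `w · X(n)` is constant, and the states equalize at the
consensus value `w · X_w / (2 − amu − bmu − cmu)` — the closed-form
after-effect. Strictly stable families (single-state, UDL, and any
fast/slow or two-state fit with spectral radius < 1) decay to zero instead;
with a retention estimate near 1 that decay can take 10⁵–10⁶ strides, so
numerical demonstrations choose the horizon from the fitted spectral
radius. Under a sustained input the modified-UDL output generally grows
linearly in `n` (`B` is outside the range of `I − A` unless
`bmu = amu + bmu − 1`), which is what lets it describe gradual,
non-exponential training responses.

Two structural identities are exploited for initialization and testing:
`cmu = 1` freezes the reference state and reproduces UDL exactly with
`(au, bu, du) = (amu, bmu, dmu)`, and both two-state specializations embed
verbatim into the general two-state family.

### Non-identifiability of the modified-UDL retentions

The family's transfer function,

    d + d [bmu z + (1 − amu − bmu − cmu + amu·cmu)] / [(z − 1)(z − λ₂)],
    λ₂ = amu + bmu + cmu − 1,

is symmetric under swapping `amu ↔ cmu`: both the free pole and the
numerator are unchanged (the cross term enters only as `amu·cmu` and
`amu + cmu`). Two different parameter vectors therefore produce *identical*
outputs for every input schedule started from rest, and a least-squares fit
lands on either branch depending on its starting point. Fitted modified-UDL
estimates are reported in a canonical orientation, `cmu ≥ amu` — the
reference state drifting no faster than the planned state, matching the
model's motivation — unless the swapped twin would violate the constraints.
This is a property of the model family, not of the optimizer; any user of
this family should be aware that only the pair {amu, cmu} is identified.

## Preprocessing

`fill_missing` interpolates interior gaps linearly against stride index and
extends end gaps with the nearest observed value (interpolation is
undefined there). `smooth_within_session` replaces each stride with the
mean of itself and ±2 neighbours *within the same session*, truncating the
window at session edges — session separation is specified, edge behaviour
is this package's choice. `reference_and_scale` subtracts the mean of
baseline strides 81–100 (the late-baseline block, after treadmill
familiarization) and divides by the sample SD (n−1 denominator) of the
referenced values from stride 81 to the end; the SD is computed after
subtraction, which fixes the scale definition without affecting the shift.
Post-conditions, enforced by tests to 1e−9: reference-window mean ≈ 0,
normalization-window SD = 1. A constant series has no scale and is
rejected.

## Estimation

The objective is the free-run simulation error: the candidate model is
simulated open-loop from a zero state at the fit-window origin (stride 81
by default) and the residual sum of squares against the observed strides is
minimized. The models carry no process-noise term, so one-step-ahead
prediction-error alternatives would require an explicit noise model the
families do not define; free-run error is the plainest reading of a
least-squares trajectory fit, and the choice is recorded here because it is
genuinely open.

Optimization uses SLSQP with box bounds plus inequality constraints:
strict orderings (`as > af`, `bf > bs`) as `≥` with margin 1e−6; the
modified-UDL free eigenvalue confined to [−1, 1]; two-state stability via
the Jury conditions `|det A| ≤ 1`, `|tr A| ≤ 1 + det A`. Each family is
restarted from `n_restarts` (default 100) uniform draws — retention-type
parameters on [0, 1], learning-type on [−1, 1], gains on [−5, 5], with
rejection resampling to feasibility; the boxes live in `FitOptions` so they
are auditable. A restart whose endpoint fails `check_constraints` is
discarded. The best RSS wins, ties within 1e−12 going to the earlier
restart; the reported RSS is recomputed by re-simulating the winning spec,
so it is exactly reproducible downstream. The single-state fit is seeded
from the best UDL estimate and the two-state fit from the best modified-UDL
*and* fast/slow realizations (each seeded spec is also evaluated directly
as a candidate), which makes the nesting inequalities
R²(super) ≥ R²(sub) − 1e−6 hold by construction.

Goodness of fit: R² = 1 − RSS/TSS about the fit-window mean (negative
values allowed; undefined and flagged NaN for constant observations), and
the least-squares AIC `n ln(RSS/n) + 2k` with `n` the number of fitted
strides and `k` the family's parameter count. Absolute AIC offsets are
irrelevant to rankings, which is all the comparison stage consumes; a
perfect fit returns −∞ with a warning.

## Group comparison

Per-metric tables (rows = fitted units, columns = the five families) pass a
Shapiro–Wilk gate at α = 0.05 applied jointly: any non-normal column sends
the metric down the nonparametric branch. Omnibus: one-way repeated-measures
ANOVA (statsmodels `AnovaRM`, no sphericity correction — recorded in the
report) or Friedman. Post-hoc: all 10 pairs by paired t or Wilcoxon
signed-rank (Pratt zero handling, recorded), flagged at the corrected
α = 0.05/10 = 0.005. A pair with all-zero differences is reported
non-significant with a diagnostic note rather than an error. Identical
columns short-circuit the Friedman statistic to (0, p = 1).

## Synthetic data

The generator emulates the study protocol — 100 baseline, 200 intervention,
100 washout strides, cohorts of 16 — with `u_level = 1` and the gain `d`
absorbing pulse magnitude and direction (responses are SD-normalized, so
physical torque units never reach the models; distinct pulse conditions are
distinct condition labels with their own parameters). Defaults, chosen once
as a realistic regime: modified-UDL truth `(amu, bmu, cmu, dmu) =
(0.6, 0.2, 0.9, 1.0)` (free eigenvalue 0.7 — a fast transient — and a
slowly drifting reference that yields a visible washout plateau),
observation noise SD 0.05 on the normalized scale, per-parameter Gaussian
jitter SD 0.02 across participants with rejection resampling at constraint
boundaries, missing-stride rate 0 (0.05 where interpolation is exercised).

Observation noise is i.i.d. Gaussian on `y`. Real stride series have
autocorrelated, possibly heteroscedastic noise and drifts the models do not
capture; the 5-stride smoothing induces short-range correlation similar to
the real pipeline's, but passing recovery tests here demonstrates
correctness of the machinery under the stated noise model, not performance
on experimental data.

## Numerical choices and problem sizes

- Stability tolerance 1e−9 on the spectral radius; after-effect formulas
  demand strict stability of all free modes and reject the degenerate
  `amu + bmu + cmu = 2` case (second unit mode).
- Native-vs-canonical equivalence is asserted to 1e−10 *relative to the
  trajectory scale* `max(1, max|y|)`: marginally stable draws ramp to
  magnitudes ~10², where an absolute 1e−10 band would sit below the float64
  accumulation floor of two differently-associated 400-step recursions.
- Parameter recovery is scored per parameter as the cohort-median absolute
  error against each participant's own jittered truth. Along the flat
  direction left by the near-degenerate likelihood the single-series ML
  estimate of `amu` has sampling SD ≈ 0.04 at noise SD 0.05, so
  worst-of-cohort error regularly exceeds 0.1 by chance; the median is the
  stable summary. Modified-UDL estimates are canonicalized (`cmu ≥ amu`)
  before scoring.
- The long-running checks use: 100 random draws per family for simulation
  equivalence (400 strides each); 16-participant cohorts at noise SD
  ∈ {0.2, 0.1, 0.05, 0} with 100 restarts per fit for recovery; 20 restarts
  per family for the nesting margins; 1000 replicate 16-row null tables for
  familywise error. These sizes give stable statistics while keeping a full
  run in the minutes range on one CPU.

## Known limitations

- Free-run least squares has no explicit noise model; standard errors for
  the fitted parameters are not produced.
- The amu↔cmu ambiguity means individual retention parameters should not be
  interpreted without the canonicalization convention in mind.
- The general two-state family is over-parameterized for its I/O behaviour
  (a transfer function needs only 5 numbers); its parameter values are not
  interpretable, only its fit quality is.
- No gait biomechanics: HE/NPI extraction from raw kinematics/kinetics, and
  any mapping from physical torque pulses to the model input, are out of
  scope.
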