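# strideadapt

State-space models of stride-by-stride motor adaptation to robot-assisted
gait training.

When a robotic exoskeleton applies torque pulses to the hip and knee during
walking, propulsion outcomes — hip extension angle at peak anterior ground
reaction force (HE) and normalized propulsive impulse (NPI) — evolve stride
by stride: they adapt during the ~200-stride training block and partially
persist (after-effects) through the washout block that follows. This package
is for researchers in neuromotor control and rehabilitation robotics who
want to fit, compare and simulate trial-by-trial models of that process.

## The models

All five families are discrete-time linear state-space systems in the stride
index `n`, with exoskeleton input `u(n)` and observed outcome `y(n)`:

    X(n+1) = A X(n) + B u(n)
    y(n+1) = C X(n+1) + D u(n+1)

| family         | free parameters | states | mechanism |
|----------------|-----------------|--------|-----------|
| `single_state` | 4 — a′, b′, c, d | 1 | error-based learning, canonical form a′ = a − b + bc, b′ = bd |
| `udl`          | 3 — au, bu, du   | 1 | use-dependent learning toward recent outputs; fixed reference x0 = 0 |
| `fast_slow`    | 5 — af, bf, as, bs, d (as > af > 0, bf > bs) | 2 | fast (high-learning/low-retention) + slow error-driven states |
| `modified_udl` | 4 — amu, bmu, cmu (∈[0,1]), dmu | 2 | use-dependent learning with a *dynamic* reference state |
| `two_state`    | 9 — all entries of A, B, C, D | 2 | fully general two-state model |

The modified-UDL model is the interesting one: its transition matrix

    A′ = [[cmu, 1 − cmu], [1 − amu − bmu, amu + bmu]]

has rows summing to 1, hence a structural eigenvalue of exactly 1. Along
that consensus mode the reference and planned states equalize, so after
training stops the output settles at

    y(∞) = [(1 − amu − bmu) x0_w + (1 − cmu) x_w] / (2 − amu − bmu − cmu)

— a persistent, generally nonzero after-effect, which strictly stable
single-state and UDL dynamics cannot produce.

The pipeline mirrors the experimental workflow: stride series are
interpolated across missing strides, smoothed with a 5-stride session-local
average, baseline-referenced on strides 81–100 and SD-normalized from
stride 81; models are fitted to strides 81 → end by constrained
least squares (SQP, 100 random restarts, stability and validity constraints,
nested families seeded from their submodels' optima) and scored with R² and
the least-squares AIC `n ln(RSS/n) + 2k`; cohort-level R²/AIC tables are
compared with a Shapiro–Wilk-gated RM-ANOVA/Friedman omnibus and paired
t/Wilcoxon post-hocs at the Bonferroni-corrected α = 0.05/10.

## A worked example

```python
import strideadapt as sa

truth = sa.default_truth()          # modified UDL: amu=0.6 bmu=0.2 cmu=0.9 dmu=1
series = sa.generate_trajectory(truth, noise_sd=0.05, seed=8)
schedule, _ = sa.build_protocol()   # 100 baseline / 200 pulse / 100 washout strides
fits = sa.fit_all_families(series, schedule, sa.FitOptions(n_restarts=30, seed=1))
for name, res in fits.items():
    print(f"{name:<14}{res.k_params:>3}{res.r2:>10.4f}{res.aic:>10.1f}")
```

prints (family, parameter count, R², AIC):

```
single_state    4    1.0000   -1841.5
udl             3    1.0000   -1843.4
fast_slow       5    0.9855      86.6
modified_udl    4    1.0000   -1904.5
two_state       9    1.0000   -1894.5
```

The data were generated by the modified-UDL model, and its fit wins on AIC:
it matches the 9-parameter two-state model's residual while paying a penalty
for only 4 parameters. The strictly stable families cannot track the
washout plateau (`fast_slow` fails badly here because the trajectory ramps
under the sustained pulse). `examples/` contains this and three more
narrated scripts (simulation, preprocessing, cohort-level comparison);
an equivalent shell workflow is available via the `strideadapt`
CLI (`synth`, `preprocess`, `simulate`, `fit`, `compare`).

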