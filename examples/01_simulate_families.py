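"""Simulate the five adaptation-model families over the training protocol.

Builds one representative spec per family, runs it over the standard
100-baseline / 200-intervention / 100-washout schedule, and prints the
response at training onset, end of training, and end of washout.  The
washout column shows the key qualitative difference: only the modified-UDL
model keeps a nonzero after-effect.
"""

import numpy as np

import strideadapt as sa

SPECS = {
    "single_state": sa.ModelSpec("single_state", {"a_prime": 0.9, "b_prime": 0.1, "c": 1.0, "d": 0.5}),
    "udl": sa.ModelSpec("udl", {"au": 0.5, "bu": 0.2, "du": 1.0}),
    "fast_slow": sa.ModelSpec("fast_slow", {"af": 0.5, "bf": 0.3, "as": 0.9, "bs": 0.1, "d": 1.0}),
    "modified_udl": sa.default_truth(),
    "two_state": sa.ModelSpec(
        "two_state",
        {"a11": 0.8, "a12": 0.05, "a21": 0.1, "a22": 0.85, "b1": 0.2, "b2": 0.1, "c1": 1.0, "c2": 0.5, "d": 1.0},
    ),
}

schedule, sessions = sa.build_protocol()
print(f"{'family':<14}{'y(101)':>9}{'y(300)':>9}{'y(400)':>9}  spectral radius")
for name, spec in SPECS.items():
    real = sa.canonical_form(spec)
    y = sa.simulate(real, schedule)
    radius = sa.eigen_analysis(real).spectral_radius
    print(f"{name:<14}{y[100]:>9.3f}{y[299]:>9.3f}{y[399]:>9.3f}  {radius:.3f}")

print()
print("y(400) is the last washout stride: families with all poles strictly")
print("inside the unit circle decay back to 0 there, while the modified-UDL")
print("model (structural unit eigenvalue) keeps a persistent after-effect.")
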