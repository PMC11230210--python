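"""Condition a noisy stride series the way the fitting pipeline expects.

Generates a modified-UDL trajectory with observation noise and 5% missing
strides, then interpolates, smooths (5-stride session-local average),
baseline-references on strides 81-100 and SD-normalizes from stride 81.
The printed post-conditions are what the estimation stage relies on.
"""

import numpy as np

import strideadapt as sa

series = sa.generate_trajectory(sa.default_truth(), noise_sd=0.3, missing_rate=0.05, seed=42)
print(f"raw series: {series.n_strides} strides, {series.missing_mask.sum()} missing")

out = sa.preprocess(series)
ref_mean = out.values[80:100].mean()
norm_sd = np.std(out.values[80:], ddof=1)
print(f"after preprocessing: reference-window mean = {ref_mean:.2e} (should be ~0)")
print(f"                     normalization-window SD = {norm_sd:.6f} (should be 1)")
print("values are now dimensionless, zero-referenced to late baseline, and")
print("unit-scaled so HE and NPI outcomes are directly comparable.")
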