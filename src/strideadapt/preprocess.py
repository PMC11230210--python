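"""Stride-series conditioning before model fitting.

The pipeline mirrors how propulsion outcomes are prepared for state-space
fitting: (1) fill missing strides by linear interpolation, (2) average each
stride with its two preceding and two subsequent strides *within the same
session*, (3) subtract the mean of late-baseline strides 81-100 so the
unperturbed response sits at zero, and (4) divide by the standard deviation
of the referenced values from stride 81 to the end, putting both HE and NPI
on a common dimensionless scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import SESSION_ORDER, StrideSeries


@dataclass
class PreprocessConfig:
    """Knobs of the conditioning pipeline.

    smoothing_half_width
        Strides averaged on each side of a stride (default 2, i.e. a
        5-stride centered window, truncated at session edges).
    reference_window
        Inclusive 1-based stride interval whose mean defines the zero
        reference; default (81, 100), the late-baseline block after
        treadmill familiarization.
    normalization_start
        1-based stride from which the normalization SD is computed
        (through the last stride); default 81.
    """

    smoothing_half_width: int = 2
    reference_window: tuple[int, int] = (81, 100)
    normalization_start: int = 81

    def __post_init__(self) -> None:
        if self.smoothing_half_width < 0:
            raise ValueError("smoothing_half_width must be >= 0")
        lo, hi = self.reference_window
        if not (1 <= lo <= hi):
            raise ValueError("invalid reference_window")
        if self.normalization_start < 1:
            raise ValueError("normalization_start must be >= 1")


def fill_missing(series: StrideSeries) -> StrideSeries:
    """Fill missing strides by linear interpolation against stride index.

    Interior gaps are interpolated linearly; leading/trailing gaps take the
    nearest observed value (linear interpolation is undefined there).
    Observed values are left untouched and the missing mask is cleared.
    """
    mask = series.missing_mask | np.isnan(series.values)
    if mask.all():
        raise ValueError("cannot interpolate an all-missing series")
    if not mask.any():
        return series.replace_values(series.values.copy())
    idx = np.arange(series.n_strides)
    filled = series.values.copy()
    filled[mask] = np.interp(idx[mask], idx[~mask], series.values[~mask])
    return series.replace_values(filled)


def smooth_within_session(series: StrideSeries, config: PreprocessConfig | None = None) -> StrideSeries:
    """Centered moving average of +/- half_width strides, session by session.

    Windows truncate at session boundaries, so no information bleeds between
    baseline, intervention and washout blocks.
    """
    config = config or PreprocessConfig()
    if np.isnan(series.values).any() or series.missing_mask.any():
        raise ValueError("smooth_within_session requires a gap-free series; run fill_missing first")
    w = 2 * config.smoothing_half_width + 1
    out = series.values.copy()
    for label in SESSION_ORDER:
        if not (series.sessions == label).any():
            continue
        sl = series.session_slice(label)
        block = pd.Series(series.values[sl])
        out[sl] = block.rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    return series.replace_values(out)


def reference_and_scale(series: StrideSeries, config: PreprocessConfig | None = None) -> StrideSeries:
    """Baseline-reference and SD-normalize a series.

    Subtracts the mean over the reference window (strides 81-100 by
    default), then divides by the sample SD of the referenced values from
    ``normalization_start`` through the last stride.  Afterwards the
    reference-window mean is ~0 and the normalization-window SD is 1.
    """
    config = config or PreprocessConfig()
    lo, hi = config.reference_window
    if series.n_strides < hi or series.n_strides < config.normalization_start:
        raise ValueError("series too short for the reference/normalization windows")
    vals = series.values - series.values[lo - 1 : hi].mean()
    tail = vals[config.normalization_start - 1 :]
    sd = float(np.std(tail, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero standard deviation over the normalization window")
    return series.replace_values(vals / sd)


def preprocess(series: StrideSeries, config: PreprocessConfig | None = None) -> StrideSeries:
    """fill_missing -> smooth_within_session -> reference_and_scale."""
    config = config or PreprocessConfig()
    out = fill_missing(series)
    out = smooth_within_session(out, config)
    return reference_and_scale(out, config)
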