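"""Long-format stride-table CSV and JSON document I/O.

The stride table has columns ``participant, condition, outcome, stride,
session, value``; one row per stride, an empty value cell marking a missing
stride.  Each (participant, condition, outcome) group becomes one
:class:`~strideadapt.series.StrideSeries`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import ModelSpec
from .series import SESSION_ORDER, StrideSeries
from .stats import ComparisonReport

STRIDE_TABLE_COLUMNS = ["participant", "condition", "outcome", "stride", "session", "value"]


def read_stride_table(path) -> list[StrideSeries]:
    """Read a long-format stride CSV into a list of stride series.

    Rows within a group are sorted by stride; strides must be consecutive
    integers starting at 1 and (participant, condition, outcome, stride)
    must be unique.  Empty value cells become missing strides.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in STRIDE_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"stride table missing columns {missing_cols}")
    bad = ~df["session"].isin(SESSION_ORDER)
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(f"unknown session label {df.loc[row, 'session']!r} at row {row}")
    if df.duplicated(subset=["participant", "condition", "outcome", "stride"]).any():
        raise ValueError("duplicate (participant, condition, outcome, stride) keys")
    out: list[StrideSeries] = []
    for (pid, cond, outc), grp in df.groupby(["participant", "condition", "outcome"], sort=True):
        grp = grp.sort_values("stride")
        strides = grp["stride"].to_numpy()
        if not np.array_equal(strides, np.arange(1, len(strides) + 1)):
            raise ValueError(
                f"strides for ({pid}, {cond}, {outc}) are not consecutive integers from 1"
            )
        values = grp["value"].to_numpy(dtype=float)
        mask = np.isnan(values)
        out.append(
            StrideSeries(
                values=values,
                sessions=grp["session"].to_numpy(dtype=object),
                participant_id=str(pid),
                condition_id=str(cond),
                outcome=str(outc),
                missing_mask=mask,
            )
        )
    return out


def write_stride_table(series: Iterable[StrideSeries] | StrideSeries, path) -> None:
    """Write stride series to the long-format CSV (missing strides as empty cells)."""
    if isinstance(series, StrideSeries):
        series = [series]
    frames = []
    for s in series:
        vals = s.values.astype(object).copy()
        frames.append(
            pd.DataFrame(
                {
                    "participant": s.participant_id,
                    "condition": s.condition_id,
                    "outcome": s.outcome,
                    "stride": s.strides,
                    "session": s.sessions,
                    "value": np.where(s.missing_mask, np.nan, s.values),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_model_spec(spec: ModelSpec, path, x_init: Sequence[float] | None = None) -> None:
    doc = spec.to_dict()
    if x_init is not None:
        doc["x_init"] = list(np.asarray(x_init, dtype=float))
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model_spec(path) -> ModelSpec:
    return ModelSpec.from_dict(json.loads(Path(path).read_text()))


def write_fit_result(result: FitResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def read_fit_result(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def write_comparison_report(report: ComparisonReport, json_path, csv_path=None) -> None:
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=2))
    if csv_path is not None:
        report.pairs_frame().to_csv(csv_path, index=False)


def fitness_table(results: Iterable[tuple[tuple[str, str, str], str, FitResult]], metric: str) -> pd.DataFrame:
    """Pivot (unit key, family, FitResult) triples into a units x families table."""
    rows: dict[tuple, dict] = {}
    for key, family, res in results:
        rows.setdefault(key, {})[family] = getattr(res, metric)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "unit"
    return df
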