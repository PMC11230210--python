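"""Synthetic gait-training cohorts from known model parameters.

The experimental protocol the generator emulates: 100 baseline strides
without torque pulses, 200 strides with a fixed torque-pulse pattern, and
100 washout strides, for a cohort of 16 healthy participants.  Observed
trajectories are model simulations plus i.i.d. Gaussian observation noise;
participants differ by Gaussian jitter on the true parameters (rejection
resampling keeps every jittered spec constraint-valid), and a fraction of
strides can be marked missing to exercise interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import ModelSpec, canonical_form, check_constraints, simulate
from .series import InputSchedule, StrideSeries


def default_truth() -> ModelSpec:
    """Default modified-UDL ground truth for synthetic studies.

    Retention amu = 0.6 and use-dependent learning bmu = 0.2 place the free
    eigenvalue at 0.7 (fast transient); reference retention cmu = 0.9 makes
    the reference state drift slowly, giving a visible washout plateau;
    dmu = 1 with unit input level leaves the pulse magnitude in the gain.
    """
    return ModelSpec("modified_udl", {"amu": 0.6, "bmu": 0.2, "cmu": 0.9, "dmu": 1.0})


@dataclass
class Protocol:
    """Torque-pulse session structure (strides per block, input level)."""

    n_baseline: int = 100
    n_intervention: int = 200
    n_washout: int = 100
    u_level: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_baseline, self.n_intervention, self.n_washout) < 0:
            raise ValueError("block lengths must be >= 0")
        if self.n_total < 1:
            raise ValueError("protocol must span at least one stride")

    @property
    def n_total(self) -> int:
        return self.n_baseline + self.n_intervention + self.n_washout


@dataclass
class CohortConfig:
    """Cohort-level generator settings."""

    n_participants: int = 16
    truth: ModelSpec = field(default_factory=default_truth)
    parameter_jitter_sd: float | Mapping[str, float] = 0.02
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def build_protocol(protocol: Protocol | None = None) -> tuple[InputSchedule, np.ndarray]:
    """Input schedule and aligned session labels for a protocol.

    u is 0 on baseline strides, ``u_level`` on intervention strides and 0 on
    washout strides.
    """
    protocol = protocol or Protocol()
    u = np.concatenate(
        [
            np.zeros(protocol.n_baseline),
            np.full(protocol.n_intervention, protocol.u_level),
            np.zeros(protocol.n_washout),
        ]
    )
    sessions = np.array(
        ["baseline"] * protocol.n_baseline
        + ["intervention"] * protocol.n_intervention
        + ["washout"] * protocol.n_washout,
        dtype=object,
    )
    return InputSchedule(u=u), sessions


def generate_trajectory(
    spec: ModelSpec,
    protocol: Protocol | None = None,
    noise_sd: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
    participant_id: str = "P01",
    condition_id: str = "C1",
    outcome: str = "HE",
) -> StrideSeries:
    """Simulate one noisy stride series from a model spec.

    y_obs(n) = y_model(n) + eps(n), eps i.i.d. N(0, noise_sd^2); a random
    ``missing_rate`` fraction of strides is marked missing (values NaN).
    Deterministic for a fixed seed.
    """
    protocol = protocol or Protocol()
    rep = check_constraints(spec)
    if not rep.valid:
        raise ValueError(f"invalid spec: {rep.violations}")
    schedule, sessions = build_protocol(protocol)
    y = simulate(canonical_form(spec), schedule)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    else:
        y = y.copy()
    mask = np.zeros(y.size, dtype=bool)
    if missing_rate > 0:
        mask = rng.random(y.size) < missing_rate
        if mask.all():  # keep at least one observation
            mask[rng.integers(y.size)] = False
        y[mask] = np.nan
    return StrideSeries(
        values=y,
        sessions=sessions,
        participant_id=participant_id,
        condition_id=condition_id,
        outcome=outcome,
        missing_mask=mask,
    )


def _jitter_spec(
    truth: ModelSpec,
    jitter_sd: float | Mapping[str, float],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> ModelSpec:
    names = list(truth.params)
    if isinstance(jitter_sd, Mapping):
        sds = np.array([float(jitter_sd.get(k, 0.0)) for k in names])
    else:
        sds = np.full(len(names), float(jitter_sd))
    base = np.array([truth.params[k] for k in names])
    for _ in range(max_tries):
        cand = ModelSpec(truth.family, dict(zip(names, base + rng.normal(0.0, 1.0, len(names)) * sds)))
        if check_constraints(cand).valid:
            return cand
    raise RuntimeError("parameter jitter kept violating constraints; reduce parameter_jitter_sd")


def generate_cohort(
    config: CohortConfig | None = None,
    protocol: Protocol | None = None,
    condition_id: str = "C1",
    outcome: str = "HE",
) -> tuple[list[StrideSeries], pd.DataFrame]:
    """A cohort of stride series plus the per-participant truth table.

    Each participant's spec is an independently jittered copy of the truth
    (resampled until it passes :func:`check_constraints`).  Returns the list
    of series and a DataFrame with one row per participant carrying the true
    parameters, for recovery scoring.
    """
    config = config or CohortConfig()
    protocol = protocol or Protocol()
    rng = np.random.default_rng(config.seed)
    series_list: list[StrideSeries] = []
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        spec_i = _jitter_spec(config.truth, config.parameter_jitter_sd, rng)
        child_seed = int(rng.integers(2**31))
        series_list.append(
            generate_trajectory(
                spec_i,
                protocol,
                noise_sd=config.noise_sd,
                missing_rate=config.missing_rate,
                seed=child_seed,
                participant_id=pid,
                condition_id=condition_id,
                outcome=outcome,
            )
        )
        rows.append({"participant": pid, "family": spec_i.family, **spec_i.params})
    return series_list, pd.DataFrame(rows)
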