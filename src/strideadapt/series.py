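"""Core containers for stride-indexed data.

A stride series is one outcome trajectory (hip extension angle, HE, or
normalized propulsive impulse, NPI) for one participant and torque-pulse
condition, indexed by stride number n = 1..N.  Session labels partition the
strides into contiguous baseline -> intervention -> washout blocks.  The
input schedule holds the exoskeleton input u driving the state-space models;
entry i of the schedule is u(i), counting from u(0), while observations run
from stride 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

SESSION_ORDER = ("baseline", "intervention", "washout")
OUTCOMES = ("HE", "NPI")


@dataclass
class StrideSeries:
    """One outcome trajectory over strides with session labels.

    Parameters
    ----------
    values : array of float
        Outcome value per stride (NaN allowed only where ``missing_mask``).
    sessions : array of str
        Per-stride session label; contiguous blocks in the order
        baseline -> intervention -> washout (any prefix/subset of that order).
    participant_id, condition_id, outcome : str
        Grouping keys; ``outcome`` is ``"HE"`` or ``"NPI"``.
    missing_mask : array of bool, optional
        True where the stride was not observed.  Defaults to all-observed.
    """

    values: np.ndarray
    sessions: np.ndarray
    participant_id: str = "P01"
    condition_id: str = "C1"
    outcome: str = "HE"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sessions = np.asarray(self.sessions, dtype=object)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if self.sessions.shape != self.values.shape:
            raise ValueError("values and sessions must have equal length")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask length mismatch")
        self._check_sessions()

    def _check_sessions(self) -> None:
        labels = list(dict.fromkeys(self.sessions.tolist()))  # order of appearance
        for lab in labels:
            if lab not in SESSION_ORDER:
                raise ValueError(f"unknown session label {lab!r}")
        # order of appearance must follow the canonical order
        order = [SESSION_ORDER.index(lab) for lab in labels]
        if order != sorted(order):
            raise ValueError("sessions must appear in baseline -> intervention -> washout order")
        # contiguity: each label occupies one block
        for lab in labels:
            idx = np.flatnonzero(self.sessions == lab)
            if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError(f"session {lab!r} strides are not contiguous")

    @property
    def n_strides(self) -> int:
        return int(self.values.size)

    @property
    def strides(self) -> np.ndarray:
        """1-based stride indices."""
        return np.arange(1, self.n_strides + 1)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.condition_id, self.outcome)

    def session_slice(self, label: str) -> slice:
        idx = np.flatnonzero(self.sessions == label)
        if idx.size == 0:
            raise KeyError(f"no strides with session {label!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def replace_values(self, values: np.ndarray, *, missing_mask: np.ndarray | None = None) -> "StrideSeries":
        """Copy of the series with new values (and optionally a new mask)."""
        if missing_mask is None:
            missing_mask = np.zeros(len(values), dtype=bool)
        return dataclasses.replace(self, values=np.asarray(values, dtype=float), missing_mask=missing_mask)


@dataclass
class InputSchedule:
    """Exoskeleton input per stride.

    ``u[i]`` is the input u(i), i = 0..N-1; it is zero outside the
    intervention block.  The schedule driving a series must have the same
    length as the series.
    """

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 1 or self.u.size == 0:
            raise ValueError("schedule must be a nonempty 1-D array")

    def __len__(self) -> int:
        return int(self.u.size)
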