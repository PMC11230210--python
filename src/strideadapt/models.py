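"""The five stride-by-stride motor-adaptation model families.

All families are discrete-time linear state-space models

    X(n+1) = A X(n) + B u(n)
    y(n+1) = C X(n+1) + D u(n+1)

with one or two states.  The stride index n plays the role of time; u is the
exoskeleton input (torque-pulse level) and y the observed propulsion outcome
(HE or NPI after normalization).

Families
--------
``single_state``
    Error-based learning with a single planned-movement state.  Fitted in its
    canonical parameterization (a', b', c, d) where a' = a - b + b c and
    b' = b d collapse the native retention/error-update pair (a, b).
``udl``
    Use-dependent learning: the planned movement is attracted toward the
    previously produced output; the reference movement x0 is fixed at 0.
    Parameters (au, bu, du).
``fast_slow``
    Two error-driven states with fast (high learning, low retention) and slow
    (low learning, high retention) dynamics; parameters (af, bf, as, bs, d)
    with as > af > 0 and bf > bs.
``modified_udl``
    Use-dependent learning with a *dynamic* reference state x0 that drifts
    toward recent outputs, giving the model a structural unit eigenvalue
    (rows of A sum to 1) and hence persistent after-effects.  Parameters
    (amu, bmu, cmu, dmu) with cmu in [0, 1].
``two_state``
    Fully general two-state model; all 9 entries of (A, B, C, D) free.

Time convention: a schedule of length N lists u(0)..u(N-1); outputs are
reported for strides n = 1..N, and the feedthrough of the final stride uses
u(N) held at the last schedule entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .series import InputSchedule

FAMILIES = ("single_state", "udl", "fast_slow", "modified_udl", "two_state")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "single_state": ("a_prime", "b_prime", "c", "d"),
    "udl": ("au", "bu", "du"),
    "fast_slow": ("af", "bf", "as", "bs", "d"),
    "modified_udl": ("amu", "bmu", "cmu", "dmu"),
    "two_state": ("a11", "a12", "a21", "a22", "b1", "b2", "c1", "c2", "d"),
}

#: Native parameterization of the single-state model: retention a, error
#: update b, output gains c and d.  Same count as the canonical form.
SINGLE_STATE_NATIVE = ("a", "b", "c", "d")

STATE_DIM = {
    "single_state": 1,
    "udl": 1,
    "fast_slow": 2,
    "modified_udl": 2,
    "two_state": 2,
}

#: Tolerance on the spectral radius: eigenvalues of magnitude <= 1 + STABILITY_TOL
#: are admitted (the modified-UDL transition matrix carries a structural
#: eigenvalue of exactly 1, so marginal stability must be allowed).
STABILITY_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """A model family tag plus its native parameter vector.

    ``params`` must carry exactly the family's parameter names
    (:data:`PARAM_NAMES`); ``single_state`` additionally accepts the native
    keys ``(a, b, c, d)``.
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        keys = frozenset(self.params)
        expected = frozenset(PARAM_NAMES[self.family])
        if keys != expected:
            if self.family == "single_state" and keys == frozenset(SINGLE_STATE_NATIVE):
                pass  # native parameterization accepted
            else:
                raise ValueError(
                    f"{self.family} expects parameters {sorted(expected)}, got {sorted(keys)}"
                )
        object.__setattr__(self, "params", {k: float(v) for k, v in self.params.items()})

    @property
    def k_params(self) -> int:
        """Number of free parameters (4, 3, 5, 4, 9 across the families)."""
        return len(PARAM_NAMES[self.family])

    @property
    def state_dim(self) -> int:
        return STATE_DIM[self.family]

    @property
    def is_native_single_state(self) -> bool:
        return self.family == "single_state" and "a" in self.params

    def param_vector(self) -> np.ndarray:
        names = SINGLE_STATE_NATIVE if self.is_native_single_state else PARAM_NAMES[self.family]
        return np.array([self.params[k] for k in names], dtype=float)

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelSpec":
        return cls(family=doc["family"], params=doc["params"])


def single_state_to_canonical(spec: ModelSpec) -> ModelSpec:
    """Convert a native single-state spec (a, b, c, d) to canonical (a', b', c, d).

    a' = a - b + b c,  b' = b d.
    """
    if spec.family != "single_state":
        raise ValueError("not a single_state spec")
    if not spec.is_native_single_state:
        return spec
    p = spec.params
    return ModelSpec(
        "single_state",
        {
            "a_prime": p["a"] - p["b"] + p["b"] * p["c"],
            "b_prime": p["b"] * p["d"],
            "c": p["c"],
            "d": p["d"],
        },
    )


@dataclass
class StateSpaceRealization:
    """Canonical matrices (A, B, C, D) plus the initial state."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: float
    x_init: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(-1)
        self.C = np.asarray(self.C, dtype=float).reshape(-1)
        self.D = float(self.D)
        self.x_init = np.asarray(self.x_init, dtype=float).reshape(-1)
        k = self.A.shape[0]
        if self.A.shape != (k, k) or self.B.size != k or self.C.size != k or self.x_init.size != k:
            raise ValueError("inconsistent state-space dimensions")
        if k not in (1, 2):
            raise ValueError("state dimension must be 1 or 2")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]


def _canonical_matrices(family: str, p: Mapping[str, float]):
    """(A, B, C, D) for a family given its canonical parameter mapping."""
    if family == "single_state":
        return ([[p["a_prime"]]], [p["b_prime"]], [p["c"]], p["d"])
    if family == "udl":
        return ([[p["au"] + p["bu"]]], [p["bu"] * p["du"]], [1.0], p["du"])
    if family == "fast_slow":
        d = p["d"]
        return (
            [[p["af"], 0.0], [0.0, p["as"]]],
            [d * p["bf"], d * p["bs"]],
            [1.0, 1.0],
            d,
        )
    if family == "modified_udl":
        amu, bmu, cmu, dmu = p["amu"], p["bmu"], p["cmu"], p["dmu"]
        return (
            [[cmu, 1.0 - cmu], [1.0 - amu - bmu, amu + bmu]],
            [dmu * (1.0 - cmu), dmu * bmu],
            [0.0, 1.0],
            dmu,
        )
    if family == "two_state":
        return (
            [[p["a11"], p["a12"]], [p["a21"], p["a22"]]],
            [p["b1"], p["b2"]],
            [p["c1"], p["c2"]],
            p["d"],
        )
    raise ValueError(f"unknown family {family!r}")


def canonical_form(spec: ModelSpec, x_init: Sequence[float] | None = None) -> StateSpaceRealization:
    """Canonical discrete-time state-space realization of a model spec.

    ``x_init`` defaults to the zero vector: baseline referencing sets the
    pre-intervention response to ~0, so simulations and fits start at rest.
    """
    if spec.is_native_single_state:
        spec = single_state_to_canonical(spec)
    A, B, C, D = _canonical_matrices(spec.family, spec.params)
    if x_init is None:
        x_init = np.zeros(STATE_DIM[spec.family])
    return StateSpaceRealization(A=A, B=B, C=C, D=D, x_init=x_init)


def _schedule_array(schedule) -> np.ndarray:
    if isinstance(schedule, InputSchedule):
        return schedule.u
    u = np.asarray(schedule, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("schedule must be a nonempty 1-D array")
    return u


def simulate(
    realization: StateSpaceRealization,
    schedule,
    return_states: bool = False,
):
    """Simulate y(1..N) from X(0) = x_init under the given input schedule.

    Iterates X(n+1) = A X(n) + B u(n), y(n+1) = C X(n+1) + D u(n+1), with
    u(n) = schedule[n] and the final feedthrough input u(N) held at the last
    schedule entry.  Returns the output array, or ``(y, states)`` with
    states[n-1] = X(n) when ``return_states``.
    """
    u = _schedule_array(schedule)
    n = u.size
    ul = u.tolist()
    u_out = ul[1:] + [ul[-1]]
    y = np.empty(n)
    k = realization.state_dim
    if k == 1:
        a = realization.A[0, 0]
        b = realization.B[0]
        c = realization.C[0]
        d = realization.D
        x = realization.x_init[0]
        if return_states:
            states = np.empty((n, 1))
            for i in range(n):
                x = a * x + b * ul[i]
                states[i, 0] = x
                y[i] = c * x + d * u_out[i]
            return y, states
        for i in range(n):
            x = a * x + b * ul[i]
            y[i] = c * x + d * u_out[i]
        return y
    a11, a12 = realization.A[0]
    a21, a22 = realization.A[1]
    b1, b2 = realization.B
    c1, c2 = realization.C
    d = realization.D
    x1, x2 = realization.x_init
    if return_states:
        states = np.empty((n, 2))
        for i in range(n):
            ui = ul[i]
            x1, x2 = a11 * x1 + a12 * x2 + b1 * ui, a21 * x1 + a22 * x2 + b2 * ui
            states[i, 0] = x1
            states[i, 1] = x2
            y[i] = c1 * x1 + c2 * x2 + d * u_out[i]
        return y, states
    for i in range(n):
        ui = ul[i]
        x1, x2 = a11 * x1 + a12 * x2 + b1 * ui, a21 * x1 + a22 * x2 + b2 * ui
        y[i] = c1 * x1 + c2 * x2 + d * u_out[i]
    return y


def simulate_native(spec: ModelSpec, schedule, x_init: Sequence[float] | None = None) -> np.ndarray:
    """Run the model family's original recursion (error signals and all).

    This is the brute-force oracle for ``simulate(canonical_form(spec))``:
    it iterates the published update equations directly, computing the error
    e(n) = y(n) - x(n) where the family uses one, rather than the collapsed
    state-space matrices.  For ``single_state`` the native (a, b, c, d)
    parameterization is accepted alongside the canonical one.
    """
    u = _schedule_array(schedule)
    n = u.size
    ul = u.tolist()
    u_out = ul[1:] + [ul[-1]]
    if x_init is None:
        x_init = np.zeros(spec.state_dim)
    x_init = np.asarray(x_init, dtype=float).reshape(-1)
    if x_init.size != spec.state_dim:
        raise ValueError("x_init dimension mismatch")
    y = np.empty(n)
    p = spec.params
    fam = spec.family

    if fam == "single_state":
        if spec.is_native_single_state:
            a, b, c, d = p["a"], p["b"], p["c"], p["d"]
            x = x_init[0]
            for i in range(n):
                y_i = c * x + d * ul[i]
                e_i = y_i - x
                x = a * x + b * e_i
                y[i] = c * x + d * u_out[i]
        else:
            a_p, b_p, c, d = p["a_prime"], p["b_prime"], p["c"], p["d"]
            x = x_init[0]
            for i in range(n):
                x = a_p * x + b_p * ul[i]
                y[i] = c * x + d * u_out[i]
        return y
    if fam == "udl":
        # x(n+1) = au x(n) + bu y(n) + (1 - au - bu) x0,  x0 = 0
        au, bu, du = p["au"], p["bu"], p["du"]
        x = x_init[0]
        for i in range(n):
            y_i = x + du * ul[i]
            x = au * x + bu * y_i
            y[i] = x + du * u_out[i]
        return y
    if fam == "fast_slow":
        af, bf, as_, bs, d = p["af"], p["bf"], p["as"], p["bs"], p["d"]
        xf, xs = x_init
        for i in range(n):
            x_plan = xf + xs
            e_i = (x_plan + d * ul[i]) - x_plan  # y(n) - x(n) = d u(n)
            xf = af * xf + bf * e_i
            xs = as_ * xs + bs * e_i
            y[i] = xf + xs + d * u_out[i]
        return y
    if fam == "modified_udl":
        amu, bmu, cmu, dmu = p["amu"], p["bmu"], p["cmu"], p["dmu"]
        x0, x = x_init
        for i in range(n):
            y_i = x + dmu * ul[i]
            x0, x = (
                cmu * x0 + (1.0 - cmu) * y_i,
                amu * x + bmu * y_i + (1.0 - amu - bmu) * x0,
            )
            y[i] = x + dmu * u_out[i]
        return y
    if fam == "two_state":
        # the general model's original recursion is the state-space form itself
        a11, a12, a21, a22 = p["a11"], p["a12"], p["a21"], p["a22"]
        b1, b2, c1, c2, d = p["b1"], p["b2"], p["c1"], p["c2"], p["d"]
        x1, x2 = x_init
        for i in range(n):
            ui = ul[i]
            x1, x2 = a11 * x1 + a12 * x2 + b1 * ui, a21 * x1 + a22 * x2 + b2 * ui
            y[i] = c1 * x1 + c2 * x2 + d * u_out[i]
        return y
    raise ValueError(f"unknown family {fam!r}")


def modified_udl_conjugate(spec: ModelSpec) -> ModelSpec:
    """The observationally equivalent modified-UDL spec with amu and cmu swapped.

    The family's transfer function

        d + d [bmu z + (1 - amu - bmu - cmu + amu cmu)] / [(z - 1)(z - lam2)],
        lam2 = amu + bmu + cmu - 1,

    is symmetric in (amu, cmu): swapping the two retention parameters gives a
    model with an identical output for every input schedule started from the
    zero state.  Parameters are therefore identifiable only up to this swap.
    """
    if spec.family != "modified_udl":
        raise ValueError("not a modified_udl spec")
    p = spec.params
    return ModelSpec(
        "modified_udl", {"amu": p["cmu"], "bmu": p["bmu"], "cmu": p["amu"], "dmu": p["dmu"]}
    )


def canonicalize_modified_udl(spec: ModelSpec) -> ModelSpec:
    """Pick the representative of the swap-equivalence class with cmu >= amu.

    The convention matches the modeling intent (the reference state drifts
    more slowly than the planned state).  If the swapped twin violates the
    family constraints (e.g. amu outside [0, 1]), the spec is returned as is.
    """
    if spec.family != "modified_udl":
        raise ValueError("not a modified_udl spec")
    if spec.params["cmu"] >= spec.params["amu"]:
        return spec
    twin = modified_udl_conjugate(spec)
    return twin if check_constraints(twin).valid else spec


@dataclass
class ConstraintReport:
    valid: bool
    violations: list = field(default_factory=list)


def check_constraints(spec: ModelSpec, tol: float = 1e-9) -> ConstraintReport:
    """Check the family's validity constraints plus stability.

    fast_slow: as > af > 0 and bf > bs; modified_udl: 0 <= cmu <= 1; every
    family: no eigenvalue of the canonical A may exceed magnitude 1 + tol
    (marginal stability is admitted — the modified-UDL A has a structural
    unit eigenvalue).
    """
    violations: list[tuple[str, float]] = []
    p = spec.params
    if spec.family == "fast_slow":
        if not p["as"] > p["af"]:
            violations.append(("as>af", p["as"] - p["af"]))
        if not p["af"] > 0:
            violations.append(("af>0", p["af"]))
        if not p["bf"] > p["bs"]:
            violations.append(("bf>bs", p["bf"] - p["bs"]))
    elif spec.family == "modified_udl":
        if not 0.0 <= p["cmu"] <= 1.0:
            violations.append(("cmu in [0,1]", p["cmu"]))
    radius = eigen_analysis(canonical_form(spec)).spectral_radius
    if radius > 1.0 + tol:
        violations.append(("stability", radius))
    return ConstraintReport(valid=not violations, violations=violations)


@dataclass
class EigenReport:
    eigenvalues: np.ndarray
    magnitudes: np.ndarray
    spectral_radius: float
    stable: bool


def eigen_analysis(realization: StateSpaceRealization, tol: float = STABILITY_TOL) -> EigenReport:
    """Eigenvalues of A; stable iff the spectral radius is <= 1 + tol."""
    eig = np.linalg.eigvals(realization.A)
    mags = np.abs(eig)
    radius = float(mags.max())
    return EigenReport(eigenvalues=eig, magnitudes=mags, spectral_radius=radius, stable=radius <= 1.0 + tol)


def after_effect_asymptote(spec: ModelSpec, state_at_washout: Sequence[float]) -> float:
    """Limit of y(n) as n -> infinity under u = 0 from the given state.

    Single-state, UDL and strictly stable fast/slow or two-state models decay
    to 0: the washout after-effect vanishes.  The modified-UDL model carries
    a structural unit eigenvalue along [1, 1]; the reference and planned
    states equalize at the consensus value

        [(1 - amu - bmu) x0_w + (1 - cmu) x_w] / (2 - amu - bmu - cmu),

    the left-eigenvector weighted average of the washout state, which is
    nonzero for generic post-training states.
    """
    state = np.asarray(state_at_washout, dtype=float).reshape(-1)
    if state.size != spec.state_dim:
        raise ValueError("state dimension mismatch")
    p = spec.params
    if spec.family == "modified_udl":
        amu, bmu, cmu = p["amu"], p["bmu"], p["cmu"]
        lam2 = amu + bmu + cmu - 1.0
        if not abs(lam2) < 1.0:
            raise ValueError("free eigenvalue amu+bmu+cmu-1 must lie strictly inside the unit circle")
        denom = 2.0 - amu - bmu - cmu
        if abs(denom) < 1e-12:
            raise ValueError("degenerate denominator: second mode is marginal (amu+bmu+cmu = 2)")
        return ((1.0 - amu - bmu) * state[0] + (1.0 - cmu) * state[1]) / denom
    rep = eigen_analysis(canonical_form(spec))
    if rep.spectral_radius >= 1.0:
        raise ValueError("after-effect limit requires strict stability in all free eigenvalues")
    return 0.0
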