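"""Linear compartmental pharmacokinetics driven by dosing-event histories.

Dosing histories (boluses, zero-order infusions, extravascular doses) are
compiled into piecewise-constant input schedules and propagated through a
1-3 compartment linear disposition model with optional first-order
absorption depot.  Between input changes the system ``x' = A x + u`` is
solved exactly: ``A`` is diagonalized once, and each constant-rate segment
is propagated in closed (modal) form, which is the matrix exponential of a
linear system written in its eigenbasis.  This keeps profiles bit-stable
and lets the dependence compartment (see :mod:`iwspkpd.dependence`) be
attached analytically.

Clearances scale allometrically with body weight (default exponent 0.75),
volumes linearly (exponent 1.0), both relative to ``reference_weight``.

Units: time is hours throughout; doses are in the drug's native dose unit
(mg or mcg); plasma concentrations in the drug's declared concentration
unit (ng/mL or mcg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DosingEvent",
    "PKParameters",
    "ConcentrationProfile",
    "InputSchedule",
    "ModalSegment",
    "compile_segments",
    "simulate_concentrations",
    "simulate_state",
    "modal_plasma",
    "evaluate_segments",
]

ROUTE_IV = "intravenous"
ROUTE_EV = "extravascular"
_ROUTES = (ROUTE_IV, ROUTE_EV)

# dose unit per litre -> concentration unit conversion factors
_UNIT_SCALE = {
    ("mg", "ng/mL"): 1000.0,   # mg/L = 1000 ng/mL
    ("mg", "mcg/mL"): 1.0,     # mg/L = mcg/mL
    ("mcg", "ng/mL"): 1.0,     # mcg/L = ng/mL
    ("mcg", "mcg/mL"): 1e-3,
}


@dataclass(frozen=True)
class DosingEvent:
    """One administration of one drug.

    ``duration == 0`` denotes a bolus; ``duration > 0`` a zero-order
    infusion of ``amount`` over ``duration`` hours.  ``amount`` is in the
    drug's native dose unit.
    """

    drug_id: str
    time: float
    amount: float
    duration: float = 0.0
    route: str = ROUTE_IV

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if self.route not in _ROUTES:
            raise ValueError(f"route must be one of {_ROUTES}")

    @property
    def rate(self) -> float:
        """Zero-order input rate (dose unit per hour); 0 for a bolus."""
        return self.amount / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class PKParameters:
    """Disposition/absorption constants of one drug at ``reference_weight``.

    ``CL``, ``Q2``, ``Q3`` in L/h; ``V_c``, ``V2``, ``V3`` in L; ``ka`` in
    1/h; ``F`` is the extravascular bioavailability fraction.  Clearance-like
    constants scale with ``(weight / reference_weight) ** exp_clearance``,
    volumes with ``** exp_volume``.
    """

    drug_id: str
    CL: float
    V_c: float
    n_compartments: int = 1
    Q2: float = 0.0
    V2: float | None = None
    Q3: float = 0.0
    V3: float | None = None
    ka: float | None = None
    F: float = 1.0
    reference_weight: float = 70.0
    exp_clearance: float = 0.75
    exp_volume: float = 1.0
    dose_unit: str = "mg"
    concentration_unit: str = "ng/mL"

    def __post_init__(self) -> None:
        if not 1 <= self.n_compartments <= 3:
            raise ValueError("n_compartments must be 1, 2 or 3")
        if self.CL <= 0 or self.V_c <= 0:
            raise ValueError("CL and V_c must be > 0")
        if self.n_compartments >= 2 and (self.Q2 <= 0 or not self.V2 or self.V2 <= 0):
            raise ValueError("2-compartment model needs Q2 > 0 and V2 > 0")
        if self.n_compartments == 3 and (self.Q3 <= 0 or not self.V3 or self.V3 <= 0):
            raise ValueError("3-compartment model needs Q3 > 0 and V3 > 0")
        if not 0 < self.F <= 1:
            raise ValueError("F must lie in (0, 1]")
        if self.ka is not None and self.ka <= 0:
            raise ValueError("ka must be > 0 when given")
        if self.reference_weight <= 0:
            raise ValueError("reference_weight must be > 0")
        if (self.dose_unit, self.concentration_unit) not in _UNIT_SCALE:
            raise ValueError(
                f"unsupported unit pair ({self.dose_unit}, {self.concentration_unit})"
            )

    @property
    def unit_scale(self) -> float:
        """Factor converting (dose unit / L) to ``concentration_unit``."""
        return _UNIT_SCALE[(self.dose_unit, self.concentration_unit)]

    def scaled(self, weight: float) -> dict:
        """Allometrically scaled constants for a patient of ``weight`` kg."""
        if weight <= 0:
            raise ValueError("weight must be > 0")
        fcl = (weight / self.reference_weight) ** self.exp_clearance
        fv = (weight / self.reference_weight) ** self.exp_volume
        return {
            "CL": self.CL * fcl,
            "Q2": self.Q2 * fcl,
            "Q3": self.Q3 * fcl,
            "V_c": self.V_c * fv,
            "V2": (self.V2 or 0.0) * fv,
            "V3": (self.V3 or 0.0) * fv,
            "ka": self.ka,
        }

    def system_matrix(self, weight: float, with_depot: bool = False) -> np.ndarray:
        """Drift matrix ``A`` of the amount-space linear system.

        State layout: central, [peripheral 2, [peripheral 3,]] [depot].
        """
        s = self.scaled(weight)
        n = self.n_compartments + (1 if with_depot else 0)
        A = np.zeros((n, n))
        A[0, 0] = -s["CL"] / s["V_c"]
        if self.n_compartments >= 2:
            A[0, 0] -= s["Q2"] / s["V_c"]
            A[0, 1] = s["Q2"] / s["V2"]
            A[1, 0] = s["Q2"] / s["V_c"]
            A[1, 1] = -s["Q2"] / s["V2"]
        if self.n_compartments == 3:
            A[0, 0] -= s["Q3"] / s["V_c"]
            A[0, 2] = s["Q3"] / s["V3"]
            A[2, 0] = s["Q3"] / s["V_c"]
            A[2, 2] = -s["Q3"] / s["V3"]
        if with_depot:
            if self.ka is None:
                raise ValueError("extravascular dosing requires ka")
            d = n - 1
            A[0, d] = self.ka
            A[d, d] = -self.ka
        return A


class ModalSegment:
    """Closed-form plasma concentration on one constant-input segment.

    ``C(t) = const + sum_m coef[m] * exp(rate[m] * (t - t0))`` on
    ``[t0, t1]``.  Rates are the (negative, real) eigenvalues of the
    disposition matrix.
    """

    __slots__ = ("t0", "t1", "const", "coef", "rate")

    def __init__(self, t0, t1, const, coef, rate):
        self.t0 = float(t0)
        self.t1 = float(t1)
        self.const = float(const)
        self.coef = np.asarray(coef, dtype=float)
        self.rate = np.asarray(rate, dtype=float)

    def __call__(self, t):
        tau = np.asarray(t, dtype=float) - self.t0
        return self.const + np.exp(np.outer(tau, self.rate)) @ self.coef


@dataclass
class ConcentrationProfile:
    """Plasma concentration-time profile of one drug on a fixed grid.

    When produced by :func:`simulate_concentrations` the profile carries the
    underlying modal segments, which downstream operations (dependence
    propagation) use to stay piecewise-exact.
    """

    drug_id: str
    times: np.ndarray
    values: np.ndarray
    concentration_unit: str = "ng/mL"
    segments: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal shape")
        if np.any(self.values < -1e-9):
            raise ValueError("concentrations must be non-negative")
        self.values = np.maximum(self.values, 0.0)


@dataclass
class InputSchedule:
    """Piecewise-constant input rates plus instantaneous state jumps.

    ``boundaries`` has length K+1; segment k covers
    ``[boundaries[k], boundaries[k+1])`` with intravenous rate
    ``iv_rates[k]`` (into the central compartment) and extravascular rate
    ``ev_rates[k]`` (into the depot, before bioavailability).  Bolus doses
    appear as jumps applied at the matching boundary.
    """

    boundaries: np.ndarray
    iv_rates: np.ndarray
    ev_rates: np.ndarray
    iv_jumps: np.ndarray
    ev_jumps: np.ndarray

    @property
    def has_extravascular(self) -> bool:
        return bool(np.any(self.ev_rates > 0) or np.any(self.ev_jumps > 0))


def compile_segments(events: Sequence[DosingEvent]) -> InputSchedule:
    """Compile dosing events into a piecewise-constant input schedule.

    Overlapping infusions of the same drug are summed.  Boluses become
    state jumps at a segment boundary.  All events are assumed to belong
    to the same drug; mixing drugs here is a caller error.
    """
    events = sorted(events, key=lambda e: e.time)
    cuts = {0.0}
    for e in events:
        cuts.add(float(e.time))
        if e.duration > 0:
            cuts.add(float(e.time + e.duration))
    boundaries = np.array(sorted(cuts))
    K = len(boundaries) - 1
    iv_rates = np.zeros(max(K, 0))
    ev_rates = np.zeros(max(K, 0))
    iv_jumps = np.zeros(len(boundaries))
    ev_jumps = np.zeros(len(boundaries))
    for e in events:
        if e.duration > 0:
            lo = np.searchsorted(boundaries, e.time)
            hi = np.searchsorted(boundaries, e.time + e.duration)
            tgt = iv_rates if e.route == ROUTE_IV else ev_rates
            tgt[lo:hi] += e.rate
        else:
            k = int(np.searchsorted(boundaries, e.time))
            tgt = iv_jumps if e.route == ROUTE_IV else ev_jumps
            tgt[k] += e.amount
    return InputSchedule(boundaries, iv_rates, ev_rates, iv_jumps, ev_jumps)


def _eigensystem(A: np.ndarray):
    lam, V = np.linalg.eig(A)
    if np.max(np.abs(lam.imag)) > 1e-9 * max(np.max(np.abs(lam.real)), 1e-12):
        return None
    lam = lam.real
    V = V.real
    if np.linalg.cond(V) > 1e10:  # near-defective: fall back to dense expm
        return None
    return lam, V, np.linalg.inv(V)


def modal_plasma(
    events: Sequence[DosingEvent],
    params: PKParameters,
    weight: float,
    t_end: float,
) -> list[ModalSegment]:
    """Exact plasma-concentration representation as modal segments.

    Covers ``[0, t_end]``; initial state is drug-free.  Raises
    ``ArithmeticError`` if the disposition matrix is too ill-conditioned to
    diagonalize reliably (callers fall back to dense propagation).
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    sched = compile_segments(events)
    if sched.has_extravascular and params.ka is None:
        raise ValueError(f"{params.drug_id}: extravascular dosing requires ka")
    with_depot = sched.has_extravascular
    A = params.system_matrix(weight, with_depot=with_depot)
    eig = _eigensystem(A)
    if eig is None:
        raise ArithmeticError("disposition matrix is not safely diagonalizable")
    lam, V, Vinv = eig
    n = A.shape[0]
    Vc = params.scaled(weight)["V_c"]
    scale = params.unit_scale / Vc

    bounds = list(sched.boundaries)
    iv_rates = list(sched.iv_rates)
    ev_rates = list(sched.ev_rates)
    if t_end > bounds[-1]:
        bounds.append(float(t_end))
        iv_rates.append(0.0)
        ev_rates.append(0.0)
    F = params.F

    segments: list[ModalSegment] = []
    x = np.zeros(n)
    for k in range(len(bounds) - 1):
        x = x.copy()
        x[0] += sched.iv_jumps[k] if k < len(sched.iv_jumps) else 0.0
        if with_depot and k < len(sched.ev_jumps):
            x[-1] += F * sched.ev_jumps[k]
        u = np.zeros(n)
        u[0] = iv_rates[k]
        if with_depot:
            u[-1] += F * ev_rates[k]
        xp = -np.linalg.solve(A, u) if np.any(u) else np.zeros(n)
        w = Vinv @ (x - xp)
        segments.append(
            ModalSegment(bounds[k], bounds[k + 1], scale * xp[0],
                         scale * V[0, :] * w, lam)
        )
        x = xp + V @ (w * np.exp(lam * (bounds[k + 1] - bounds[k])))
    if not segments:  # no events at all
        segments.append(ModalSegment(0.0, max(t_end, 0.0) or 1.0,
                                     0.0, np.zeros(1), -np.ones(1)))
    return segments


def evaluate_segments(segments: list[ModalSegment], times: np.ndarray) -> np.ndarray:
    """Evaluate a modal plasma representation at arbitrary times."""
    times = np.asarray(times, dtype=float)
    starts = np.array([s.t0 for s in segments])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)
    out = np.empty_like(times)
    for k in np.unique(idx):
        m = idx == k
        out[m] = segments[k](times[m])
    return np.maximum(out, 0.0)


def simulate_concentrations(
    events: Sequence[DosingEvent],
    params: PKParameters,
    weight: float,
    grid: np.ndarray,
) -> ConcentrationProfile:
    """Plasma concentration over time for one drug.

    Solves the linear compartmental system piecewise-exactly between input
    changes and evaluates it on ``grid`` (strictly increasing hours).  The
    returned profile carries the modal segments for downstream exact use.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < 0:
        raise ValueError("grid times must be >= 0")
    try:
        segments = modal_plasma(events, params, weight, t_end=float(grid[-1]))
    except ArithmeticError:
        values = _simulate_dense(events, params, weight, grid)
        return ConcentrationProfile(
            params.drug_id, grid, values,
            concentration_unit=params.concentration_unit, segments=None,
        )
    values = evaluate_segments(segments, grid)
    return ConcentrationProfile(
        params.drug_id, grid, values,
        concentration_unit=params.concentration_unit, segments=segments,
    )


def _simulate_dense(events, params, weight, grid):
    """Fallback: dense matrix-exponential stepping over merged time points."""
    sched = compile_segments(events)
    with_depot = sched.has_extravascular
    A = params.system_matrix(weight, with_depot=with_depot)
    n = A.shape[0]
    Vc = params.scaled(weight)["V_c"]
    scale = params.unit_scale / Vc
    F = params.F

    pts = np.union1d(sched.boundaries, grid)
    pts = pts[pts <= grid[-1] + 1e-12]
    if pts[0] > 0:
        pts = np.concatenate([[0.0], pts])
    x = np.zeros(n)
    out = {}
    for i, t in enumerate(pts):
        k = np.searchsorted(sched.boundaries, t)
        if k < len(sched.boundaries) and np.isclose(sched.boundaries[k], t):
            x[0] += sched.iv_jumps[k]
            if with_depot:
                x[-1] += F * sched.ev_jumps[k]
        out[t] = scale * x[0]
        if i + 1 < len(pts):
            seg = np.searchsorted(sched.boundaries, t, side="right") - 1
            u = np.zeros(n)
            if 0 <= seg < len(sched.iv_rates):
                u[0] = sched.iv_rates[seg]
                if with_depot:
                    u[-1] += F * sched.ev_rates[seg]
            dt = pts[i + 1] - t
            M = np.zeros((n + 1, n + 1))
            M[:n, :n] = A
            M[:n, n] = u
            E = expm(M * dt)
            x = E[:n, :n] @ x + E[:n, n]
    return np.array([out[t] for t in grid])


def simulate_state(
    events: Sequence[DosingEvent],
    params: PKParameters,
    weight: float,
    grid: np.ndarray,
) -> dict:
    """Amount-space trajectories plus cumulative elimination (diagnostic).

    Returns a dict with ``times``, ``amounts`` (grid x compartments, in the
    dose unit), ``eliminated`` (cumulative) and ``input`` (cumulative dosed
    amount after bioavailability).  Used for mass-balance checks.
    """
    grid = np.asarray(grid, dtype=float)
    sched = compile_segments(events)
    with_depot = sched.has_extravascular
    A = params.system_matrix(weight, with_depot=with_depot)
    n = A.shape[0]
    s = params.scaled(weight)
    F = params.F

    # augment with an elimination accumulator
    Ae = np.zeros((n + 1, n + 1))
    Ae[:n, :n] = A
    Ae[n, 0] = s["CL"] / s["V_c"]

    pts = np.union1d(sched.boundaries, grid)
    pts = pts[pts <= grid[-1] + 1e-12]
    if pts[0] > 0:
        pts = np.concatenate([[0.0], pts])
    x = np.zeros(n + 1)
    cum_in = 0.0
    states, cum_ins = {}, {}
    for i, t in enumerate(pts):
        k = np.searchsorted(sched.boundaries, t)
        if k < len(sched.boundaries) and np.isclose(sched.boundaries[k], t):
            x[0] += sched.iv_jumps[k]
            cum_in += sched.iv_jumps[k]
            if with_depot:
                x[n - 1] += F * sched.ev_jumps[k]
                cum_in += F * sched.ev_jumps[k]
        states[t] = x.copy()
        cum_ins[t] = cum_in
        if i + 1 < len(pts):
            seg = np.searchsorted(sched.boundaries, t, side="right") - 1
            u = np.zeros(n + 1)
            if 0 <= seg < len(sched.iv_rates):
                u[0] = sched.iv_rates[seg]
                if with_depot:
                    u[n - 1] += F * sched.ev_rates[seg]
            dt = pts[i + 1] - t
            M = np.zeros((n + 2, n + 2))
            M[: n + 1, : n + 1] = Ae
            M[: n + 1, n + 1] = u
            E = expm(M * dt)
            x = E[: n + 1, : n + 1] @ x + E[: n + 1, n + 1]
            cum_in += u[:n].sum() * dt
    X = np.array([states[t] for t in grid])
    return {
        "times": grid,
        "amounts": X[:, :n],
        "eliminated": X[:, n],
        "input": np.array([cum_ins[t] for t in grid]),
    }
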