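"""Dependence compartment, concentration shortage and overall severity.

The hypothetical dependence concentration tracks plasma with first-order
kinetics::

    dC_dependence/dt = k_dep * (C_plasma - C_dependence)

so ``C_dependence`` represents the exposure level a patient has adapted to.
When plasma falls below it, the *shortage* ``C_dependence - C_plasma``
drives withdrawal severity linearly (zero effect while plasma covers the
dependence level).  Per-drug effects add to a lognormally distributed
individual baseline:

    lambda_i = typical_baseline * exp(eta_i) + sum_j slope_j * shortage_j

Propagation is exact: plasma profiles produced by :mod:`iwspkpd.pk` carry a
piecewise sum-of-exponentials representation, for which the relaxation ODE
has a closed-form solution on every segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pk import ConcentrationProfile, ModalSegment

__all__ = [
    "DependenceParams",
    "DependenceProfile",
    "IndividualBaseline",
    "propagate_dependence",
    "dependence_on_segments",
    "drug_effect",
    "shortage",
    "total_severity",
]


@dataclass(frozen=True)
class DependenceParams:
    """Per-drug dependence rate constant and severity slope."""

    drug_id: str
    k_dep: float
    slope: float

    def __post_init__(self) -> None:
        if self.k_dep <= 0:
            raise ValueError("k_dep must be > 0")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")


@dataclass
class DependenceProfile:
    """Dependence-compartment concentration on the same grid as the plasma
    profile it was propagated from (same unit as plasma)."""

    drug_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-9):
            raise ValueError("dependence concentrations must be non-negative")
        self.values = np.maximum(self.values, 0.0)


@dataclass(frozen=True)
class IndividualBaseline:
    """Typical baseline severity with an individual lognormal deviation."""

    typical_baseline: float
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.typical_baseline <= 0:
            raise ValueError("typical_baseline must be > 0")

    @property
    def realized(self) -> float:
        return self.typical_baseline * np.exp(self.eta)


def dependence_on_segments(
    segments: list[ModalSegment],
    k_dep: float,
    times: np.ndarray,
    initial: float = 0.0,
) -> np.ndarray:
    """Exact dependence concentration at ``times`` given modal plasma segments.

    On a segment where ``C_plasma(tau) = a + sum_m b_m exp(l_m tau)`` the
    relaxation ODE has the closed form::

        C_dep(tau) = a + sum_m p_m exp(l_m tau) + r exp(-k tau)

    with ``p_m = k b_m / (k + l_m)`` and ``r`` fixed by continuity; modes
    with ``l_m ~ -k`` degenerate to a ``k b_m tau exp(-k tau)`` term.
    """
    if k_dep <= 0:
        raise ValueError("k_dep must be > 0")
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    starts = np.array([s.t0 for s in segments])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(segments) - 1)

    c0 = float(initial)
    for k, seg in enumerate(segments):
        lam = seg.rate
        b = seg.coef
        denom = k_dep + lam
        degen = np.abs(denom) < 1e-10 * max(k_dep, 1.0)
        p = np.where(degen, 0.0, k_dep * b / np.where(degen, 1.0, denom))
        r = c0 - seg.const - p.sum()

        sel = idx == k
        if np.any(sel):
            tau = times[sel] - seg.t0
            vals = seg.const + np.exp(np.outer(tau, lam)) @ p + r * np.exp(-k_dep * tau)
            if np.any(degen):
                bd = b[degen]
                vals += (k_dep * bd.sum()) * tau * np.exp(-k_dep * tau)
            out[sel] = vals
        # advance the continuity state to the segment end
        dtau = seg.t1 - seg.t0
        c0 = seg.const + float(np.exp(lam * dtau) @ p) + r * np.exp(-k_dep * dtau)
        if np.any(degen):
            c0 += k_dep * b[degen].sum() * dtau * np.exp(-k_dep * dtau)
    return np.maximum(out, 0.0)


def _dependence_piecewise_linear(times, cplasma, k_dep, initial):
    """Exact relaxation assuming plasma is piecewise linear between samples."""
    out = np.empty_like(cplasma)
    c = float(initial)
    out[0] = c if times[0] > 0 else float(initial)
    # treat the value at the first sample as the initial condition
    out[0] = c
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        c0p = cplasma[i]
        m = (cplasma[i + 1] - c0p) / dt
        # particular solution c0p + m*tau - m/k; homogeneous decay of the rest
        c = c0p + m * dt - m / k_dep + (c - c0p + m / k_dep) * np.exp(-k_dep * dt)
        out[i + 1] = c
    return np.maximum(out, 0.0)


def propagate_dependence(
    profile: ConcentrationProfile,
    k_dep: float,
    initial_C_dep: float = 0.0,
) -> DependenceProfile:
    """Propagate the dependence compartment along a plasma profile.

    Uses the profile's exact modal segments when available (piecewise-exact
    joint solution of PK + dependence); otherwise falls back to exact
    integration of a piecewise-linear interpolant of the sampled plasma
    curve.  The output shares the input grid.
    """
    if k_dep <= 0:
        raise ValueError("k_dep must be > 0")
    if initial_C_dep < 0:
        raise ValueError("initial_C_dep must be >= 0")
    if profile.segments is not None:
        vals = dependence_on_segments(profile.segments, k_dep, profile.times, initial_C_dep)
    else:
        vals = _dependence_piecewise_linear(
            profile.times, profile.values, k_dep, initial_C_dep
        )
    return DependenceProfile(profile.drug_id, profile.times, vals)


def shortage(c_dep, c_plasma):
    """Concentration shortage ``max(0, C_dependence - C_plasma)``."""
    return np.maximum(np.asarray(c_dep, dtype=float) - np.asarray(c_plasma, dtype=float), 0.0)


def drug_effect(c_dep, c_plasma, slope: float):
    """Severity contribution of one drug: ``slope * shortage`` (zero-floored).

    Exactly zero whenever ``C_dependence <= C_plasma`` — ongoing treatment
    that covers the dependence level causes no withdrawal.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    return slope * shortage(c_dep, c_plasma)


def total_severity(baseline: IndividualBaseline, effects) -> np.ndarray | float:
    """Overall severity ``lambda = baseline * exp(eta) + sum_j effect_j``.

    ``effects`` is an iterable of per-drug contributions (scalars or arrays
    on a shared grid); all must be non-negative.
    """
    total = baseline.realized
    for e in effects:
        e = np.asarray(e, dtype=float)
        if np.any(e < 0):
            raise ValueError("drug effects must be non-negative")
        total = total + e
    return total
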