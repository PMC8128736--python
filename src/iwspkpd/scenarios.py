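"""Weaning scenarios: schedule construction and typical-patient risk curves.

A scenario is a constant-rate treatment phase followed either by an abrupt
stop or by stepwise reductions of a fixed fraction of the *initial* rate at
a fixed interval (the weaning style most protocols use).  Risk over time is
simulated for a typical patient — no inter-individual variability (eta = 0)
and no Markov conditioning — by chaining the PK engine, the dependence
compartment and the truncated generalized Poisson tail probability
P(score > 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dependence import dependence_on_segments
from .params import IWSParams
from .pk import DosingEvent, PKParameters, evaluate_segments, modal_plasma
from .scores import gp_truncated_pmf_matrix

__all__ = ["WeaningScenario", "RiskCurve", "build_schedule", "simulate_risk",
           "compare_strategies", "baseline_risk"]


@dataclass(frozen=True)
class WeaningScenario:
    """A single-drug treatment + weaning schedule for one patient.

    ``initial_rate_per_kg`` is in the drug's dose unit per kg per hour
    (e.g. 0.02 mg/kg/h morphine, 1.5 mcg/kg/h fentanyl).  During weaning
    the infusion drops by ``step_fraction`` of the *initial* rate every
    ``step_interval_h`` hours until it reaches zero; ``abrupt=True`` stops
    the infusion in one step at the end of the treatment phase.
    """

    drug_id: str
    weight: float
    initial_rate_per_kg: float
    treatment_duration_h: float
    step_fraction: float = 0.1
    step_interval_h: float = 24.0
    abrupt: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.initial_rate_per_kg < 0:
            raise ValueError("rate must be >= 0")
        if self.treatment_duration_h <= 0:
            raise ValueError("treatment duration must be > 0")
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must lie in (0, 1]")
        if self.step_interval_h <= 0:
            raise ValueError("step_interval_h must be > 0")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.abrupt:
            return f"{self.drug_id} abrupt stop"
        return (f"{self.drug_id} {self.step_fraction:.0%} "
                f"every {self.step_interval_h:g} h")

    @property
    def schedule_end_h(self) -> float:
        """Time at which the infusion rate reaches zero."""
        if self.abrupt:
            return self.treatment_duration_h
        n_steps = math.ceil(1.0 / self.step_fraction) - 1
        return self.treatment_duration_h + n_steps * self.step_interval_h


def build_schedule(scenario: WeaningScenario) -> list[DosingEvent]:
    """Expand a scenario into dosing events (one per constant-rate period)."""
    rate0 = scenario.initial_rate_per_kg * scenario.weight
    if rate0 == 0:
        return []
    events = [
        DosingEvent(
            scenario.drug_id, 0.0, rate0 * scenario.treatment_duration_h,
            duration=scenario.treatment_duration_h,
        )
    ]
    if scenario.abrupt:
        return events
    t = scenario.treatment_duration_h
    rate = rate0
    while True:
        rate = rate - scenario.step_fraction * rate0
        if rate <= 1e-12 * rate0:
            break
        events.append(
            DosingEvent(
                scenario.drug_id, t, rate * scenario.step_interval_h,
                duration=scenario.step_interval_h,
            )
        )
        t += scenario.step_interval_h
    return events


@dataclass
class RiskCurve:
    """P(score > 3) over time with companion concentration curves."""

    scenario: WeaningScenario
    times: np.ndarray
    risk: np.ndarray
    c_plasma: np.ndarray
    c_dependence: np.ndarray
    baseline_risk: float

    @property
    def peak_risk(self) -> float:
        return float(self.risk.max())

    @property
    def time_of_peak(self) -> float:
        return float(self.times[int(np.argmax(self.risk))])

    @property
    def auc_above_baseline(self) -> float:
        """Time integral (probability x hours) of risk above baseline."""
        return float(np.trapezoid(np.maximum(self.risk - self.baseline_risk, 0.0),
                                  self.times))

    def time_above(self, multiple: float = 1.5) -> float:
        """Total hours during which risk exceeds ``multiple`` x baseline."""
        above = self.risk > multiple * self.baseline_risk
        if not above.any():
            return 0.0
        dt = np.gradient(self.times)
        return float((dt * above).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "c_plasma": self.c_plasma,
                "c_dependence": self.c_dependence,
                "risk_above_3": self.risk,
            }
        )


def baseline_risk(iws: IWSParams) -> float:
    """P(score > 3) for a typical drug-free patient."""
    pmf = gp_truncated_pmf_matrix(np.array([iws.typical_baseline]), iws.delta)[0]
    return float(pmf[4:].sum())


def simulate_risk(
    scenario: WeaningScenario,
    pk_params: PKParameters,
    iws: IWSParams,
    grid_step_h: float = 0.5,
    follow_up_h: float | None = None,
) -> RiskCurve:
    """Forward-simulate a typical patient's withdrawal risk over time.

    The grid runs from 0 to the end of the schedule plus ``follow_up_h``
    (default: long enough for the dependence compartment to wash out,
    5 half-times of ``k_dep``, at least 72 h).
    """
    if scenario.drug_id not in iws.drug_effects:
        raise ValueError(f"no withdrawal parameters for drug {scenario.drug_id!r}")
    if pk_params.drug_id != scenario.drug_id:
        raise ValueError("pk_params drug does not match scenario drug")
    eff = iws.drug_effects[scenario.drug_id]
    if follow_up_h is None:
        follow_up_h = max(72.0, 5.0 * np.log(2.0) / eff.k_dep)
    t_end = scenario.schedule_end_h + follow_up_h
    grid = np.arange(0.0, t_end + grid_step_h / 2, grid_step_h)
    if grid[0] == 0.0:
        grid = grid  # concentration defined from admission

    events = build_schedule(scenario)
    if events:
        segments = modal_plasma(events, pk_params, scenario.weight, t_end=t_end)
        cp = evaluate_segments(segments, grid)
        cd = dependence_on_segments(segments, eff.k_dep, grid)
    else:
        cp = np.zeros_like(grid)
        cd = np.zeros_like(grid)
    lam = iws.typical_baseline + eff.slope * np.maximum(cd - cp, 0.0)
    pmf = gp_truncated_pmf_matrix(lam, iws.delta)
    risk = pmf[:, 4:].sum(axis=1)
    return RiskCurve(scenario, grid, risk, cp, cd, baseline_risk(iws))


def compare_strategies(
    scenarios: list[WeaningScenario],
    pk_params: PKParameters,
    iws: IWSParams,
    grid_step_h: float = 0.5,
    baseline_multiple: float = 1.5,
) -> pd.DataFrame:
    """Summarize several weaning strategies for the same drug.

    Returns one row per scenario with peak risk, its timing, the risk AUC
    above baseline, and the time spent above ``baseline_multiple`` x the
    baseline risk.  Deterministic given the inputs.
    """
    if len(scenarios) < 2:
        raise ValueError("need at least two scenarios to compare")
    drugs = {s.drug_id for s in scenarios}
    if len(drugs) != 1:
        raise ValueError("all scenarios must use the same drug")
    rows = []
    for s in scenarios:
        rc = simulate_risk(s, pk_params, iws, grid_step_h=grid_step_h)
        rows.append(
            {
                "scenario": s.name,
                "peak_risk": rc.peak_risk,
                "time_of_peak_h": rc.time_of_peak,
                "risk_auc_above_baseline": rc.auc_above_baseline,
                f"hours_above_{baseline_multiple:g}x_baseline": rc.time_above(baseline_multiple),
            }
        )
    return pd.DataFrame(rows)
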