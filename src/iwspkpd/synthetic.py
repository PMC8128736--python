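"""Fully synthetic PICU cohorts with the statistical structure the model assumes.

The generator emulates a pediatric intensive-care cohort: lognormal body
weights (median ~11 kg, wide spread), multi-week continuous infusions of
morphine / fentanyl / ketamine with stepwise weaning (occasionally an
abrupt stop), withdrawal scores observed on a fixed interval (default 8 h),
a lognormal individual baseline deviation, and scores drawn sequentially
through the full model chain — PK, dependence compartment, severity, and
the Markov-inflated truncated generalized Poisson conditioned on the
previously *sampled* score.  Everything is reproducible from the seed.

What it deliberately does not emulate: the score-responsive up/down
titration of real bedside practice (dosing here follows fixed randomized
templates), rater effects, and co-medication beyond the templated drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortDataset, Patient
from .dependence import dependence_on_segments
from .params import IWSParams, published_params
from .pk import PKParameters, evaluate_segments, modal_plasma
from .scenarios import WeaningScenario, build_schedule
from .scores import gp_truncated_pmf_matrix, markov_inflate, sample_score

__all__ = [
    "DrugTemplate",
    "CohortConfig",
    "default_templates",
    "default_pk_parameters",
    "recovery_template",
    "generate_cohort",
    "cohort_summary",
]


def default_pk_parameters() -> dict[str, PKParameters]:
    """Illustrative pediatric PK parameter sets for the three template drugs.

    These are editable stand-ins in the range of published pediatric
    models (reference weight 70 kg, allometric scaling CL ~ WT^0.75,
    V ~ WT^1.0); every analysis that depends on PK values states them
    explicitly rather than relying on these defaults silently.
    """
    return {
        "morphine": PKParameters(
            drug_id="morphine", n_compartments=2, CL=60.0, V_c=150.0,
            Q2=30.0, V2=100.0, ka=1.0, F=0.3,
            dose_unit="mg", concentration_unit="ng/mL",
        ),
        "fentanyl": PKParameters(
            drug_id="fentanyl", n_compartments=2, CL=50.0, V_c=100.0,
            Q2=200.0, V2=250.0,
            dose_unit="mcg", concentration_unit="ng/mL",
        ),
        "ketamine": PKParameters(
            drug_id="ketamine", n_compartments=1, CL=80.0, V_c=150.0,
            dose_unit="mg", concentration_unit="mcg/mL",
        ),
    }


@dataclass(frozen=True)
class DrugTemplate:
    """Randomized treatment template for one drug.

    Each treated patient receives a constant infusion at a lognormally
    distributed per-kg rate for a uniformly distributed number of days,
    then weans stepwise (``step_fraction`` of the initial rate every
    ``step_interval_h``); with probability ``abrupt_prob`` the infusion is
    stopped abruptly instead.  Observation continues ``follow_up_h`` past
    the end of the schedule.
    """

    drug_id: str
    probability: float = 1.0
    rate_per_kg_median: float = 0.02
    rate_gsd: float = 1.4
    treatment_days_min: float = 14.0
    treatment_days_max: float = 28.0
    step_fraction: float = 0.1
    step_interval_h: float = 24.0
    abrupt_prob: float = 0.2
    follow_up_h: float = 120.0

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        if self.rate_per_kg_median < 0 or self.rate_gsd < 1:
            raise ValueError("invalid rate distribution")
        if self.treatment_days_min < 0 or self.treatment_days_max < self.treatment_days_min:
            raise ValueError("invalid treatment duration range")


def default_templates() -> dict[str, DrugTemplate]:
    """Templates emulating the reference cohort's drug use.

    Drug prevalences follow the cohort (morphine and fentanyl in ~9 of 10
    patients, ketamine in ~6 of 10); median per-kg rates sit below the
    weaning-simulation scenarios because observed cumulative doses imply
    mostly moderate infusion rates; treatment durations span the 5-day
    inclusion minimum to three weeks.  Follow-up after drug stop is longer
    for the slowly equilibrating drugs so the resolution of dependence is
    observed.
    """
    return {
        "morphine": DrugTemplate(
            "morphine", probability=0.93, rate_per_kg_median=0.008,
            rate_gsd=2.0, treatment_days_min=5.0, treatment_days_max=21.0,
            step_fraction=0.1, step_interval_h=24.0, follow_up_h=240.0,
        ),
        "fentanyl": DrugTemplate(
            "fentanyl", probability=0.94, rate_per_kg_median=1.0,
            rate_gsd=2.0, treatment_days_min=5.0, treatment_days_max=21.0,
            step_fraction=0.1, step_interval_h=24.0, follow_up_h=96.0,
        ),
        "ketamine": DrugTemplate(
            "ketamine", probability=0.60, rate_per_kg_median=0.5,
            rate_gsd=2.0, treatment_days_min=5.0, treatment_days_max=21.0,
            step_fraction=0.1, step_interval_h=24.0, follow_up_h=168.0,
        ),
    }


def recovery_template(drug_id: str) -> DrugTemplate:
    """Single-drug template for parameter-recovery experiments.

    Every patient receives the drug (14-28-day treatment at the
    simulation-scenario rates, stepwise 10%-per-24 h weaning with a 20%
    chance of an abrupt stop) so the cohort is maximally informative about
    that drug's dependence dynamics; follow-up is long enough for the
    dependence compartment to resolve.
    """
    spec = {
        "morphine": dict(rate_per_kg_median=0.02, follow_up_h=240.0),
        "fentanyl": dict(rate_per_kg_median=1.5, follow_up_h=96.0),
        "ketamine": dict(rate_per_kg_median=1.0, follow_up_h=168.0),
    }
    if drug_id not in spec:
        raise KeyError(f"no recovery template for drug {drug_id!r}")
    return DrugTemplate(
        drug_id, probability=1.0, rate_gsd=1.4,
        treatment_days_min=14.0, treatment_days_max=28.0,
        step_fraction=0.1, step_interval_h=24.0, abrupt_prob=0.2,
        **spec[drug_id],
    )


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort (the seed is mandatory)."""

    n_patients: int
    seed: int
    templates: tuple[DrugTemplate, ...] = ()
    iws: IWSParams = field(default_factory=published_params)
    pk: dict[str, PKParameters] = field(default_factory=default_pk_parameters)
    weight_median_kg: float = 11.0
    weight_log_sd: float = 0.89
    weight_range_kg: tuple[float, float] = (2.4, 70.0)
    obs_interval_h: float = 8.0
    min_stay_h: float = 168.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.obs_interval_h <= 0:
            raise ValueError("obs_interval_h must be > 0")
        if not self.templates:
            object.__setattr__(
                self, "templates", tuple(default_templates().values())
            )


def generate_cohort(config: CohortConfig, return_truth: bool = False):
    """Draw a fully synthetic cohort from the generating model.

    Returns the :class:`~iwspkpd.cohort.CohortDataset`; with
    ``return_truth=True`` also a dict of ground truth (per-patient eta,
    the generating parameter vector, the seed) for recovery studies.
    Identical configs produce byte-identical datasets.
    """
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.n_patients)
    iws = config.iws
    infl = iws.inflation()
    patients, etas = [], []

    for i in range(config.n_patients):
        rng = np.random.default_rng(child_seeds[i])
        w = float(np.exp(rng.normal(np.log(config.weight_median_kg),
                                    config.weight_log_sd)))
        w = float(np.clip(w, *config.weight_range_kg))

        events = []
        per_drug = []  # (drug_id, segments, k_dep, slope)
        t_end = config.min_stay_h
        for tpl in config.templates:
            if rng.random() >= tpl.probability:
                continue
            rate = tpl.rate_per_kg_median * float(
                np.exp(rng.normal(0.0, np.log(tpl.rate_gsd)))
            )
            days = float(rng.uniform(tpl.treatment_days_min, tpl.treatment_days_max))
            scenario = WeaningScenario(
                drug_id=tpl.drug_id, weight=w, initial_rate_per_kg=rate,
                treatment_duration_h=24.0 * days,
                step_fraction=tpl.step_fraction,
                step_interval_h=tpl.step_interval_h,
                abrupt=bool(rng.random() < tpl.abrupt_prob),
            )
            ev = build_schedule(scenario)
            events += ev
            t_end = max(t_end, scenario.schedule_end_h + tpl.follow_up_h)
        events.sort(key=lambda e: e.time)

        obs_times = np.arange(config.obs_interval_h, t_end + 1e-9,
                              config.obs_interval_h)
        eta = float(rng.normal(0.0, iws.omega_baseline))
        lam = iws.typical_baseline * np.exp(eta) * np.ones(obs_times.size)
        for tpl in config.templates:
            d = tpl.drug_id
            ev_d = [e for e in events if e.drug_id == d]
            if not ev_d or d not in iws.drug_effects:
                continue
            eff = iws.drug_effects[d]
            segs = modal_plasma(ev_d, config.pk[d], w, t_end=float(obs_times[-1]))
            cp = evaluate_segments(segs, obs_times)
            cd = dependence_on_segments(segs, eff.k_dep, obs_times)
            lam += eff.slope * np.maximum(cd - cp, 0.0)

        base_pmfs = gp_truncated_pmf_matrix(lam, iws.delta)
        scores = np.empty(obs_times.size, dtype=int)
        prev = None
        for k in range(obs_times.size):
            pmf = base_pmfs[k]
            if prev is not None:
                pmf = markov_inflate(pmf, prev, infl)
            scores[k] = sample_score(pmf, rng)
            prev = int(scores[k])

        patients.append(
            Patient(
                patient_id=f"P{i + 1:03d}", weight=w, events=events,
                obs_times=obs_times, scores=scores,
            )
        )
        etas.append(eta)

    dataset = CohortDataset(patients)
    if return_truth:
        truth = {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "iws_params": iws.to_dict(),
            "eta": etas,
        }
        return dataset, truth
    return dataset


def cohort_summary(dataset: CohortDataset) -> dict:
    """Descriptive statistics of a cohort's withdrawal burden."""
    n_obs = dataset.n_observations
    if dataset.n_patients == 0 or n_obs == 0:
        return {
            "n_patients": dataset.n_patients,
            "n_observations": n_obs,
            "fraction_scores_above_3": 0.0,
            "fraction_patients_ever_above_3": 0.0,
            "median_iws_observations_per_patient": 0.0,
        }
    above = [p.scores > 3 for p in dataset.patients]
    n_above = int(sum(a.sum() for a in above))
    return {
        "n_patients": dataset.n_patients,
        "n_observations": n_obs,
        "fraction_scores_above_3": n_above / n_obs,
        "fraction_patients_ever_above_3":
            sum(bool(a.any()) for a in above) / dataset.n_patients,
        "median_iws_observations_per_patient":
            float(np.median([int(a.sum()) for a in above])),
    }
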