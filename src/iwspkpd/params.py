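"""Parameter containers for the withdrawal-severity model.

The model ties together, per drug, a first-order *dependence* rate constant
``k_dep`` (1/h) and a linear *slope* (reciprocal concentration units) that
converts the concentration shortage ``max(0, C_dependence - C_plasma)`` into
a contribution to the overall withdrawal severity ``lambda``.  Shared across
drugs are the typical baseline severity of a drug-free patient, the lognormal
inter-individual variability (IIV) of that baseline, the generalized-Poisson
dispersion coefficient ``delta`` and the Markov probability-inflation
parameters for serial correlation between consecutive scores.

:func:`published_params` returns the reference estimates obtained in a
pediatric intensive-care cohort (morphine, fentanyl and ketamine retained in
the final model); these drive the synthetic-data generator and the weaning
simulations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = [
    "DrugEffectParams",
    "IWSParams",
    "published_params",
    "cv_to_omega",
    "omega_to_cv",
    "load_iws_params",
]

#: Concentration units in which drug-effect slopes may be expressed.
CONCENTRATION_UNITS = ("ng/mL", "mcg/mL")


def cv_to_omega(cv_percent: float) -> float:
    """Convert a lognormal coefficient of variation (in %) to the SD of eta.

    Uses the exact lognormal relation ``CV = sqrt(exp(omega^2) - 1)``.
    """
    if cv_percent < 0:
        raise ValueError("CV% must be non-negative")
    return math.sqrt(math.log(1.0 + (cv_percent / 100.0) ** 2))


def omega_to_cv(omega: float) -> float:
    """Inverse of :func:`cv_to_omega` (returns percent)."""
    return 100.0 * math.sqrt(math.expm1(omega**2))


@dataclass(frozen=True)
class DrugEffectParams:
    """Dependence dynamics and severity slope for a single drug.

    Parameters
    ----------
    k_dep:
        First-order equilibration rate constant (1/h) between plasma and the
        hypothetical dependence compartment.  Controls how fast dependence
        builds up during treatment and resolves after weaning.
    slope:
        Linear gain from concentration shortage to severity, in the
        reciprocal of ``concentration_unit`` (ml/ng or ml/mcg).
    concentration_unit:
        Native plasma-concentration unit for this drug; must match the unit
        the drug's PK model reports.
    """

    k_dep: float
    slope: float
    concentration_unit: str = "ng/mL"

    def __post_init__(self) -> None:
        if self.k_dep <= 0:
            raise ValueError(f"k_dep must be > 0, got {self.k_dep}")
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0, got {self.slope}")
        if self.concentration_unit not in CONCENTRATION_UNITS:
            raise ValueError(
                f"concentration_unit must be one of {CONCENTRATION_UNITS}"
            )


@dataclass(frozen=True)
class IWSParams:
    """Full parameter vector of the withdrawal-severity model.

    ``pi_pm`` is the shared probability inflation for scores one or two
    points away from the previous score (the two are constrained equal).
    """

    typical_baseline: float
    omega_baseline: float
    delta: float
    pi_same_prev0: float
    pi_same_prevx: float
    pi_pm: float
    drug_effects: dict[str, DrugEffectParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.typical_baseline <= 0:
            raise ValueError("typical_baseline must be > 0")
        if self.omega_baseline < 0:
            raise ValueError("omega_baseline must be >= 0")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must lie in [0, 1)")
        for name in ("pi_same_prev0", "pi_same_prevx", "pi_pm"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        # Worst-case applicable inflation mass must stay below 1:
        # previous score 0 retains {0,+1,+2}; an interior score retains 5
        # targets of which 4 carry pi_pm.
        if self.pi_same_prev0 + 2 * self.pi_pm >= 1:
            raise ValueError("pi_same_prev0 + 2*pi_pm must be < 1")
        if self.pi_same_prevx + 4 * self.pi_pm >= 1:
            raise ValueError("pi_same_prevx + 4*pi_pm must be < 1")

    @property
    def cv_percent(self) -> float:
        """Baseline IIV expressed as a lognormal CV%."""
        return omega_to_cv(self.omega_baseline)

    def inflation(self):
        """The Markov inflation parameters as a :class:`~iwspkpd.scores.MarkovInflation`."""
        from .scores import MarkovInflation

        return MarkovInflation(
            pi_same_prev0=self.pi_same_prev0,
            pi_same_prevx=self.pi_same_prevx,
            pi_pm1=self.pi_pm,
            pi_pm2=self.pi_pm,
        )

    def with_drugs(self, drug_ids) -> "IWSParams":
        """Restrict the drug-effect dictionary to ``drug_ids``."""
        return replace(
            self,
            drug_effects={d: self.drug_effects[d] for d in drug_ids},
        )

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "typical_baseline": self.typical_baseline,
            "iiv_baseline_cv_percent": self.cv_percent,
            "omega_baseline": self.omega_baseline,
            "delta": self.delta,
            "pi_same_prev0": self.pi_same_prev0,
            "pi_same_prevx": self.pi_same_prevx,
            "pi_pm": self.pi_pm,
            "drug_effects": {
                d: {
                    "k_dep": e.k_dep,
                    "slope": e.slope,
                    "concentration_unit": e.concentration_unit,
                }
                for d, e in self.drug_effects.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IWSParams":
        if "omega_baseline" in d:
            omega = float(d["omega_baseline"])
        elif "iiv_baseline_cv_percent" in d:
            omega = cv_to_omega(float(d["iiv_baseline_cv_percent"]))
        else:
            raise KeyError("need omega_baseline or iiv_baseline_cv_percent")
        effects = {
            drug: DrugEffectParams(
                k_dep=float(e["k_dep"]),
                slope=float(e["slope"]),
                concentration_unit=e.get("concentration_unit", "ng/mL"),
            )
            for drug, e in d.get("drug_effects", {}).items()
        }
        return cls(
            typical_baseline=float(d["typical_baseline"]),
            omega_baseline=omega,
            delta=float(d["delta"]),
            pi_same_prev0=float(d["pi_same_prev0"]),
            pi_same_prevx=float(d["pi_same_prevx"]),
            pi_pm=float(d["pi_pm"]),
            drug_effects=effects,
        )

    def save(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))


def load_iws_params(path) -> IWSParams:
    """Load an :class:`IWSParams` vector from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return IWSParams.from_dict(data)


def published_params() -> IWSParams:
    """Reference parameter estimates from a pediatric ICU cohort.

    Final model: three drugs with quantifiable withdrawal dynamics.
    Fentanyl equilibrates fast (half-time ~2.9 h); morphine and ketamine
    much more slowly (half-times ~82 h and ~39 h).  Slopes are in the
    reciprocal of each drug's native concentration unit.
    """
    return IWSParams(
        typical_baseline=0.564,
        omega_baseline=cv_to_omega(114.0),  # ~0.9126
        delta=0.428,
        pi_same_prev0=0.401,
        pi_same_prevx=0.216,
        pi_pm=0.0698,
        drug_effects={
            "fentanyl": DrugEffectParams(0.242, 5.93, "ng/mL"),
            "morphine": DrugEffectParams(0.00848, 0.0687, "ng/mL"),
            "ketamine": DrugEffectParams(0.0180, 1.59, "mcg/mL"),
        },
    )
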