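import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from iwspkpd.params import (DrugEffectParams, IWSParams, cv_to_omega,
                            published_params)
from iwspkpd.pk import DosingEvent, PKParameters
from iwspkpd.synthetic import default_pk_parameters


@pytest.fixture(scope="session")
def reference_params() -> IWSParams:
    """The published withdrawal-model parameter vector."""
    return published_params()


@pytest.fixture(scope="session")
def pk_defaults():
    return default_pk_parameters()


@pytest.fixture
def one_comp() -> PKParameters:
    """Simple 1-compartment drug at reference weight: CL 10 L/h, V 20 L."""
    return PKParameters(drug_id="drugA", CL=10.0, V_c=20.0,
                        dose_unit="mg", concentration_unit="ng/mL")


@pytest.fixture
def neutral_start() -> IWSParams:
    """Deliberately off-truth starting values for fits."""
    return IWSParams(
        typical_baseline=1.0, omega_baseline=0.5, delta=0.2,
        pi_same_prev0=0.3, pi_same_prevx=0.15, pi_pm=0.05,
    )


def random_pk_params(rng: np.random.Generator, n_compartments: int,
                     with_depot: bool = False) -> PKParameters:
    """Randomized but physiologically plausible PK parameter sets."""
    kw = dict(
        drug_id="rand",
        n_compartments=n_compartments,
        CL=float(rng.uniform(5.0, 80.0)),
        V_c=float(rng.uniform(10.0, 300.0)),
        dose_unit="mg",
        concentration_unit="ng/mL",
    )
    if n_compartments >= 2:
        kw.update(Q2=float(rng.uniform(5.0, 100.0)), V2=float(rng.uniform(20.0, 400.0)))
    if n_compartments == 3:
        kw.update(Q3=float(rng.uniform(2.0, 50.0)), V3=float(rng.uniform(50.0, 800.0)))
    if with_depot:
        kw.update(ka=float(rng.uniform(0.2, 3.0)), F=float(rng.uniform(0.3, 1.0)))
    return PKParameters(**kw)


def random_schedule(rng: np.random.Generator, drug_id="rand",
                    allow_ev=False) -> list[DosingEvent]:
    """A few randomized boluses and infusions inside [0, 120] h."""
    events = []
    for _ in range(rng.integers(2, 6)):
        t = float(rng.uniform(0, 80))
        if rng.random() < 0.4:
            events.append(DosingEvent(drug_id, t, float(rng.uniform(1, 20))))
        else:
            route = "extravascular" if (allow_ev and rng.random() < 0.5) else "intravenous"
            events.append(
                DosingEvent(drug_id, t, float(rng.uniform(5, 100)),
                            duration=float(rng.uniform(2, 40)), route=route)
            )
    return events
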