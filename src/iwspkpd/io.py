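"""Dataset readers/writers and parameter-file handling.

The cohort file is a single long-format CSV in the pharmacometric layout::

    ID,TIME,DRUG,AMT,DUR,ROUTE,WT,AGE,DV,MDV

Dosing rows carry ``MDV=1`` with ``DRUG``, ``AMT`` (dose units), ``DUR``
(hours; 0 = bolus) and ``ROUTE``; observation rows carry ``MDV=0`` with the
integer score in ``DV`` and empty dosing columns.  Comma separated, ``.``
decimal, times in hours since admission, ``WT`` in kg repeated on every
row of a patient.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, Patient
from .pk import ROUTE_EV, ROUTE_IV, DosingEvent, PKParameters

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_pk_params",
    "write_pk_params",
    "default_pk_param_path",
    "default_iws_param_path",
]

COLUMNS = ["ID", "TIME", "DRUG", "AMT", "DUR", "ROUTE", "WT", "AGE", "DV", "MDV"]


def write_cohort(dataset: CohortDataset, path) -> None:
    """Write a cohort to the long-format CSV dialect."""
    rows = []
    for p in dataset.patients:
        for e in p.events:
            rows.append(
                {
                    "ID": p.patient_id, "TIME": e.time, "DRUG": e.drug_id,
                    "AMT": e.amount, "DUR": e.duration, "ROUTE": e.route,
                    "WT": p.weight, "AGE": p.age_months, "DV": None, "MDV": 1,
                }
            )
        for t, s in zip(p.obs_times, p.scores):
            rows.append(
                {
                    "ID": p.patient_id, "TIME": t, "DRUG": None, "AMT": None,
                    "DUR": None, "ROUTE": None, "WT": p.weight,
                    "AGE": p.age_months, "DV": int(s), "MDV": 0,
                }
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.sort_values(["ID", "TIME", "MDV"], kind="stable", inplace=True)
    df.to_csv(path, index=False)


def read_cohort(path, known_drugs=None) -> CohortDataset:
    """Read and validate a cohort CSV.

    Malformed rows fail hard with the offending CSV line number: unknown
    drug identifiers (when ``known_drugs`` is given), non-integer or
    out-of-range scores, and non-increasing observation times per patient
    are all rejected.
    """
    df = pd.read_csv(path, dtype={"ID": str, "DRUG": str, "ROUTE": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    patients = []
    for pid, grp in df.groupby("ID", sort=True):
        events = []
        obs_t, obs_y = [], []
        weight = None
        age = None
        for idx, row in grp.iterrows():
            line = idx + 2  # header + 1-based
            if weight is None and np.isfinite(row["WT"]):
                weight = float(row["WT"])
            if age is None and pd.notna(row["AGE"]):
                age = float(row["AGE"])
            mdv = int(row["MDV"])
            if mdv == 1:
                if pd.isna(row["DRUG"]) or pd.isna(row["AMT"]):
                    raise ValueError(f"{path} line {line}: dosing row needs DRUG and AMT")
                drug = str(row["DRUG"])
                if known_drugs is not None and drug not in known_drugs:
                    raise ValueError(f"{path} line {line}: unknown drug {drug!r}")
                route = row["ROUTE"] if pd.notna(row["ROUTE"]) else ROUTE_IV
                if route not in (ROUTE_IV, ROUTE_EV):
                    raise ValueError(f"{path} line {line}: bad route {route!r}")
                dur = float(row["DUR"]) if pd.notna(row["DUR"]) else 0.0
                try:
                    events.append(
                        DosingEvent(drug, float(row["TIME"]), float(row["AMT"]),
                                    duration=dur, route=route)
                    )
                except ValueError as exc:
                    raise ValueError(f"{path} line {line}: {exc}") from exc
            elif mdv == 0:
                dv = row["DV"]
                if pd.isna(dv):
                    raise ValueError(f"{path} line {line}: observation row needs DV")
                dvf = float(dv)
                if dvf != int(dvf) or not 0 <= dvf <= 10:
                    raise ValueError(
                        f"{path} line {line}: DV must be an integer score 0..10, got {dv}"
                    )
                obs_t.append(float(row["TIME"]))
                obs_y.append(int(dvf))
            else:
                raise ValueError(f"{path} line {line}: MDV must be 0 or 1")
        if weight is None:
            raise ValueError(f"{path}: patient {pid} has no weight")
        order = np.argsort(obs_t, kind="stable")
        t = np.asarray(obs_t)[order]
        y = np.asarray(obs_y, dtype=int)[order]
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: patient {pid} has non-increasing observation times")
        events.sort(key=lambda e: e.time)
        patients.append(Patient(str(pid), weight, events, t, y, age_months=age))
    return CohortDataset(patients)


# ------------------------------------------------------------- parameters

def _read_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_pk_params(path) -> dict[str, PKParameters]:
    """Load per-drug PK parameters from a YAML/JSON file keyed by drug id."""
    data = _read_structured(path)
    out = {}
    for drug, spec in data.items():
        kw = dict(spec)
        kw.setdefault("drug_id", drug)
        out[drug] = PKParameters(**kw)
    return out


def write_pk_params(params: dict[str, PKParameters], path) -> None:
    data = {}
    for drug, p in params.items():
        d = {
            "drug_id": p.drug_id, "n_compartments": p.n_compartments,
            "CL": p.CL, "V_c": p.V_c,
            "reference_weight": p.reference_weight,
            "exp_clearance": p.exp_clearance, "exp_volume": p.exp_volume,
            "dose_unit": p.dose_unit, "concentration_unit": p.concentration_unit,
            "F": p.F,
        }
        if p.n_compartments >= 2:
            d.update(Q2=p.Q2, V2=p.V2)
        if p.n_compartments == 3:
            d.update(Q3=p.Q3, V3=p.V3)
        if p.ka is not None:
            d["ka"] = p.ka
        data[drug] = d
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_pk_param_path() -> Path:
    """Path of the editable illustrative PK parameter file shipped with the package."""
    return Path(__file__).parent / "data" / "pk_defaults.yaml"


def default_iws_param_path() -> Path:
    """Path of the shipped reference withdrawal-model parameter file."""
    return Path(__file__).parent / "data" / "iws_reference.yaml"
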