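"""Cohort data containers: per-patient dosing histories and score series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import DosingEvent

__all__ = ["Patient", "CohortDataset"]


@dataclass
class Patient:
    """One patient: body weight, dosing events and ordered score observations."""

    patient_id: str
    weight: float
    events: list[DosingEvent] = field(default_factory=list)
    obs_times: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    age_months: float | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"{self.patient_id}: weight must be > 0")
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.scores = np.asarray(self.scores)
        if self.obs_times.size != self.scores.size:
            raise ValueError(f"{self.patient_id}: times and scores differ in length")
        if self.obs_times.size and np.any(np.diff(self.obs_times) <= 0):
            raise ValueError(f"{self.patient_id}: observation times must be strictly increasing")
        if self.scores.size:
            if not np.issubdtype(self.scores.dtype, np.integer):
                as_int = self.scores.astype(int)
                if np.any(as_int != self.scores):
                    raise ValueError(f"{self.patient_id}: scores must be integers")
                self.scores = as_int
            if self.scores.min() < 0 or self.scores.max() > 10:
                raise ValueError(f"{self.patient_id}: scores must lie in 0..10")

    def events_for(self, drug_id: str) -> list[DosingEvent]:
        return [e for e in self.events if e.drug_id == drug_id]

    @property
    def drug_ids(self) -> set[str]:
        return {e.drug_id for e in self.events}


@dataclass
class CohortDataset:
    """A collection of patients analysed together."""

    patients: list[Patient]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_observations(self) -> int:
        return int(sum(p.obs_times.size for p in self.patients))

    @property
    def drug_ids(self) -> set[str]:
        ids: set[str] = set()
        for p in self.patients:
            ids |= p.drug_ids
        return ids

    def __iter__(self):
        return iter(self.patients)
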