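"""Longitudinal cohort containers: per-subject volume series plus dose events."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk import DoseSchedule

__all__ = ["Subject", "CohortDataset"]


@dataclass(frozen=True)
class Subject:
    """One animal: id, observation times (days), volumes (cm^3), dose schedule."""

    id: str
    times: np.ndarray
    volumes: np.ndarray
    doses: DoseSchedule = field(default_factory=DoseSchedule)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if times.shape != volumes.shape or times.ndim != 1:
            raise ValueError(f"subject {self.id}: times and volumes must be equal-length 1-D arrays")
        if len(times) and np.any(np.diff(times) <= 0.0):
            raise ValueError(f"subject {self.id}: observation times must be strictly increasing")
        if np.any(volumes <= 0.0):
            raise ValueError(f"subject {self.id}: volumes must be positive")

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CohortDataset:
    """An ordered collection of subjects; the unit of I/O and fitting."""

    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(volumes, doses) DataFrames in the interchange CSV layout."""
        vol_rows = [
            {"subject_id": s.id, "time_days": t, "volume_cm3": v}
            for s in self.subjects
            for t, v in zip(s.times, s.volumes)
        ]
        dose_rows = [
            {"subject_id": s.id, "time_days": e.time, "dose_mg_per_kg": e.amount}
            for s in self.subjects
            for e in s.doses.events
        ]
        return (
            pd.DataFrame(vol_rows, columns=["subject_id", "time_days", "volume_cm3"]),
            pd.DataFrame(dose_rows, columns=["subject_id", "time_days", "dose_mg_per_kg"]),
        )

    @classmethod
    def from_frames(
        cls, volumes: pd.DataFrame, doses: pd.DataFrame | None = None, k_elim: float | None = None
    ) -> "CohortDataset":
        """Build a dataset from interchange DataFrames (see :mod:`dlgrowth.io`)."""
        from .pk import CPT11_HALF_LIFE_DAYS, DoseEvent, decay_rate_from_half_life

        k = decay_rate_from_half_life(CPT11_HALF_LIFE_DAYS) if k_elim is None else k_elim
        dose_map: dict[str, list[DoseEvent]] = {}
        if doses is not None and len(doses):
            for _, row in doses.iterrows():
                dose_map.setdefault(str(row["subject_id"]), []).append(
                    DoseEvent(float(row["time_days"]), float(row["dose_mg_per_kg"]))
                )
        subjects = []
        for sid, grp in volumes.groupby("subject_id", sort=False):
            subjects.append(
                Subject(
                    id=str(sid),
                    times=grp["time_days"].to_numpy(dtype=float),
                    volumes=grp["volume_cm3"].to_numpy(dtype=float),
                    doses=DoseSchedule(events=tuple(dose_map.get(str(sid), ())), k_elim=k),
                )
            )
        return cls(subjects=tuple(subjects))
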