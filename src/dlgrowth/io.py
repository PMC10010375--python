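"""CSV interchange formats, run configuration, and run records.

Longitudinal CSV: columns ``subject_id, time_days, volume_cm3``.
Dose CSV: columns ``subject_id, time_days, dose_mg_per_kg``.
Both require headers; validation errors cite the offending file line
(1-based, counting the header).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import CohortDataset
from .pk import CPT11_HALF_LIFE_DAYS, decay_rate_from_half_life

__all__ = ["read_cohort", "write_cohort", "RunConfig", "load_config", "write_run_record"]

log = logging.getLogger("dlgrowth")

VOLUME_COLUMNS = ("subject_id", "time_days", "volume_cm3")
DOSE_COLUMNS = ("subject_id", "time_days", "dose_mg_per_kg")


class CohortValidationError(ValueError):
    """A malformed record in an interchange CSV, citing its line."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_cohort(volumes_path, doses_path=None, k_elim: float | None = None) -> CohortDataset:
    """Read and validate a cohort from its volume (and optional dose) CSV.

    Raises :class:`CohortValidationError` naming the file line of the
    first offending record (non-positive volume, unsorted times within a
    subject, negative dose).
    """
    volumes_path = Path(volumes_path)
    vols = pd.read_csv(volumes_path)
    _check_columns(vols, VOLUME_COLUMNS, volumes_path)
    bad = vols.index[~(pd.to_numeric(vols["volume_cm3"], errors="coerce") > 0.0)]
    if len(bad):
        raise CohortValidationError(
            f"{volumes_path} line {bad[0] + 2}: volume_cm3 must be positive, got {vols.loc[bad[0], 'volume_cm3']!r}"
        )
    for sid, grp in vols.groupby("subject_id", sort=False):
        t = grp["time_days"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0.0):
            k = int(np.nonzero(np.diff(t) <= 0.0)[0][0]) + 1
            raise CohortValidationError(
                f"{volumes_path} line {grp.index[k] + 2}: times for subject {sid!r} must be strictly increasing"
            )

    doses = None
    if doses_path is not None:
        doses_path = Path(doses_path)
        doses = pd.read_csv(doses_path)
        _check_columns(doses, DOSE_COLUMNS, doses_path)
        badd = doses.index[pd.to_numeric(doses["dose_mg_per_kg"], errors="coerce") < 0.0]
        if len(badd):
            raise CohortValidationError(
                f"{doses_path} line {badd[0] + 2}: dose_mg_per_kg must be non-negative"
            )
        unknown = set(doses["subject_id"].astype(str)) - set(vols["subject_id"].astype(str))
        if unknown:
            raise CohortValidationError(f"{doses_path}: dose rows for unknown subject(s) {sorted(unknown)}")
    return CohortDataset.from_frames(vols, doses, k_elim=k_elim)


def write_cohort(cohort: CohortDataset, volumes_path, doses_path=None) -> None:
    """Write a cohort to the interchange CSV pair (round-trips with read_cohort)."""
    vols, doses = cohort.to_frames()
    vols.to_csv(volumes_path, index=False)
    if doses_path is not None:
        doses.to_csv(doses_path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration (model, parameters, SAEM settings, seed)."""

    model: str = "dl"
    params: dict = field(default_factory=dict)
    saem: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "runs"
    pk_half_life_days: float = CPT11_HALF_LIFE_DAYS

    @property
    def k_elim(self) -> float:
        return decay_rate_from_half_life(self.pk_half_life_days)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    return RunConfig(**raw)


def write_run_record(outdir, command: str, seed: int, config: dict) -> Path:
    """Persist a machine-readable record sufficient to reproduce the run."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {"command": command, "seed": int(seed), "package_version": __version__, "config": config}
    path = outdir / "run_record.json"
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    log.info("run record written to %s", path)
    return path
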