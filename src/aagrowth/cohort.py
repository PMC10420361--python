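"""Core containers for longitudinal aortic-diameter surveillance data.

A cohort is a list of :class:`PatientSeries`, each holding one patient's
time-ordered maximal aortic diameter measurements (cm) together with
per-patient covariates. Times are expressed in years since that patient's
first recorded measurement; calendar dates in input tables are converted
using 365.25 days per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

__all__ = [
    "DAYS_PER_YEAR",
    "PatientSeries",
    "Cohort",
    "read_cohort",
    "cohort_to_frame",
    "covariates_to_frame",
    "write_cohort",
]


class CohortFormatError(ValueError):
    """Raised when an input table lacks required columns."""


class CohortValidationError(ValueError):
    """Raised when a measurement violates a data invariant (e.g. d <= 0)."""


@dataclass(frozen=True)
class PatientSeries:
    """One patient's ordered diameter measurements plus covariates.

    Parameters
    ----------
    patient_id
        Unique identifier.
    times_yr
        Measurement times in years since the patient's first measurement;
        strictly increasing, first entry >= 0.
    diameters_cm
        Maximal aortic diameter at each time, cm; strictly positive.
    covariates
        Per-patient clinical variables (bool/str for categorical, float for
        numeric; NaN marks a missing numeric value).
    age_at_detection_yr
        Patient age at the first measurement, if known.
    modalities
        Optional imaging-modality tag per measurement (inert metadata).
    truth
        Generative ground truth when the series is synthetic.
    """

    patient_id: str
    times_yr: np.ndarray
    diameters_cm: np.ndarray
    covariates: dict = field(default_factory=dict)
    age_at_detection_yr: float | None = None
    modalities: tuple | None = None
    truth: object | None = None

    def __post_init__(self):
        t = np.asarray(self.times_yr, dtype=float)
        d = np.asarray(self.diameters_cm, dtype=float)
        if t.ndim != 1 or d.shape != t.shape:
            raise CohortValidationError(
                f"patient {self.patient_id}: times and diameters must be "
                f"1-d arrays of equal length"
            )
        if t.size and t[0] < 0:
            raise CohortValidationError(
                f"patient {self.patient_id}: negative time {t[0]}"
            )
        if np.any(np.diff(t) <= 0):
            raise CohortValidationError(
                f"patient {self.patient_id}: times must be strictly increasing"
            )
        if np.any(d <= 0):
            bad = int(np.argmax(d <= 0))
            raise CohortValidationError(
                f"patient {self.patient_id}: non-positive diameter "
                f"{d[bad]} at row {bad}"
            )
        object.__setattr__(self, "times_yr", t)
        object.__setattr__(self, "diameters_cm", d)

    @property
    def n(self) -> int:
        return self.times_yr.size

    @property
    def detection_diameter_cm(self) -> float:
        """Diameter at the first recorded measurement."""
        return float(self.diameters_cm[0])

    def with_measurements(
        self, times_yr: np.ndarray, diameters_cm: np.ndarray
    ) -> "PatientSeries":
        """Copy of this series with replaced measurement arrays."""
        return replace(
            self,
            times_yr=np.asarray(times_yr, dtype=float),
            diameters_cm=np.asarray(diameters_cm, dtype=float),
            modalities=None,
        )


Cohort = list  # a cohort is a plain list of PatientSeries


def _times_from_column(col: pd.Series) -> np.ndarray:
    """Convert a date-or-year column to years since the group's first entry."""
    if np.issubdtype(col.dtype, np.number):
        vals = col.to_numpy(dtype=float)
        return vals - vals.min()
    dates = pd.to_datetime(col)
    days = (dates - dates.min()).dt.total_seconds() / 86400.0
    return days.to_numpy() / DAYS_PER_YEAR


def read_cohort(
    measurements: pd.DataFrame | str | Path,
    covariates: pd.DataFrame | str | Path | None = None,
) -> list[PatientSeries]:
    """Assemble a cohort from a long-format measurement table.

    ``measurements`` needs columns ``patient_id``, ``diameter_cm`` and one of
    ``time_yr`` (years) or ``date`` (parseable calendar date); an optional
    ``modality`` column is carried as an inert tag. ``covariates`` is keyed by
    ``patient_id``; an ``age_at_detection_yr`` column is split out into the
    dedicated field. Covariate rows without measurements are ignored with a
    logged warning.
    """
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.read_csv(measurements)
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.read_csv(covariates)

    required = {"patient_id", "diameter_cm"}
    missing = required - set(measurements.columns)
    if missing:
        raise CohortFormatError(f"measurement table missing columns: {sorted(missing)}")
    if "time_yr" not in measurements.columns and "date" not in measurements.columns:
        raise CohortFormatError("measurement table needs a 'time_yr' or 'date' column")

    bad = measurements["diameter_cm"] <= 0
    if bad.any():
        row = measurements.index[bad][0]
        pid = measurements.loc[row, "patient_id"]
        raise CohortValidationError(
            f"non-positive diameter {measurements.loc[row, 'diameter_cm']} "
            f"for patient {pid} at input row {row}"
        )

    cov_map: dict[str, dict] = {}
    age_map: dict[str, float] = {}
    if covariates is not None:
        if "patient_id" not in covariates.columns:
            raise CohortFormatError("covariate table missing 'patient_id' column")
        known = set(measurements["patient_id"].astype(str))
        for _, row in covariates.iterrows():
            pid = str(row["patient_id"])
            if pid not in known:
                logger.warning("covariate row for unknown patient %s ignored", pid)
                continue
            vals = row.drop(labels=["patient_id"]).to_dict()
            if "age_at_detection_yr" in vals:
                age = vals.pop("age_at_detection_yr")
                if pd.notna(age):
                    age_map[pid] = float(age)
            cov_map[pid] = vals

    time_col = "time_yr" if "time_yr" in measurements.columns else "date"
    out: list[PatientSeries] = []
    for pid, grp in measurements.groupby("patient_id", sort=True):
        pid = str(pid)
        t = _times_from_column(grp[time_col])
        order = np.argsort(t, kind="stable")
        t = t[order]
        d = grp["diameter_cm"].to_numpy(dtype=float)[order]
        modal = None
        if "modality" in grp.columns:
            modal = tuple(grp["modality"].to_numpy()[order])
        out.append(
            PatientSeries(
                patient_id=pid,
                times_yr=t,
                diameters_cm=d,
                covariates=cov_map.get(pid, {}),
                age_at_detection_yr=age_map.get(pid),
                modalities=modal,
            )
        )
    return out


def cohort_to_frame(cohort: Iterable[PatientSeries]) -> pd.DataFrame:
    """Long-format measurement table (one row per measurement)."""
    rows = []
    for s in cohort:
        for i in range(s.n):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "time_yr": s.times_yr[i],
                    "diameter_cm": s.diameters_cm[i],
                    "modality": s.modalities[i] if s.modalities else "",
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "time_yr", "diameter_cm", "modality"])


def covariates_to_frame(cohort: Iterable[PatientSeries]) -> pd.DataFrame:
    """Wide per-patient covariate table, including age at detection."""
    rows = []
    for s in cohort:
        row = {"patient_id": s.patient_id, **s.covariates}
        if s.age_at_detection_yr is not None:
            row["age_at_detection_yr"] = s.age_at_detection_yr
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: Sequence[PatientSeries],
    measurements_path: str | Path,
    covariates_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> None:
    """Write the cohort as measurement / covariate / optional truth CSVs."""
    cohort_to_frame(cohort).to_csv(measurements_path, index=False)
    if covariates_path is not None:
        covariates_to_frame(cohort).to_csv(covariates_path, index=False)
    if truth_path is not None:
        rows = []
        for s in cohort:
            if s.truth is not None:
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "a_true": s.truth.a_true,
                        "b_true": s.truth.b_true,
                        "detection_diameter_cm": s.truth.detection_diameter_cm,
                    }
                )
        pd.DataFrame(rows).to_csv(truth_path, index=False)
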