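"""Preprocessing, filtering and dataset-construction rules.

Implements the cohort curation used by every experiment: merging of
measurements taken close together in time, minimum-measurement filters, the
left/right endpoint-censored dataset pair for the stability experiment, and
the train/target splits (with a two-year forecast gap) for the forecasting
experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import DAYS_PER_YEAR, PatientSeries

logger = logging.getLogger(__name__)

__all__ = [
    "merge_close_measurements",
    "filter_min_measurements",
    "make_censored_datasets",
    "make_forecast_splits",
    "ForecastSplit",
]


def merge_close_measurements(
    series: PatientSeries, window_days: float = 150.0
) -> PatientSeries:
    """Average together measurements less than ``window_days`` apart.

    Greedy left-to-right clustering: a point joins the current cluster when
    its gap to the previous cluster member is below the window, so chains of
    close points collapse into one cluster even when the endpoints are far
    apart. Each cluster is replaced by a single measurement at the mean time
    with the mean diameter. Guards against extreme slopes from back-to-back
    imaging. Idempotent, and consecutive output gaps are >= the window.
    """
    if series.n <= 1:
        return series
    window_yr = window_days / DAYS_PER_YEAR
    t, d = series.times_yr, series.diameters_cm
    clusters: list[list[int]] = [[0]]
    for i in range(1, series.n):
        if t[i] - t[clusters[-1][-1]] < window_yr:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    if len(clusters) == series.n:
        return series
    new_t = np.array([t[c].mean() for c in clusters])
    new_d = np.array([d[c].mean() for c in clusters])
    return series.with_measurements(new_t, new_d)


def filter_min_measurements(cohort: list[PatientSeries], k: int) -> list[PatientSeries]:
    """Keep only patients with at least ``k`` measurements."""
    if k < 1:
        raise ValueError("k must be at least 1")
    kept = [s for s in cohort if s.n >= k]
    logger.info("filter_min_measurements(k=%d): %d of %d patients kept", k, len(kept), len(cohort))
    return kept


def make_censored_datasets(
    cohort: list[PatientSeries],
) -> tuple[list[PatientSeries], list[PatientSeries], list[PatientSeries]]:
    """Build the (full, left-censored, right-censored) dataset triple.

    Left-censoring removes each patient's earliest measurement (an aneurysm
    detected late in its course); right-censoring removes the latest (not
    yet followed to a large size). Every patient must have >= 3 measurements
    so both censored series retain >= 2. Times keep the original origin:
    all five growth models are translation-invariant in time, and a common
    origin keeps per-patient rate deltas directly comparable.
    """
    for s in cohort:
        if s.n < 3:
            raise ValueError(
                f"patient {s.patient_id} has {s.n} < 3 measurements; "
                "filter the cohort before censoring"
            )
    left = [s.with_measurements(s.times_yr[1:], s.diameters_cm[1:]) for s in cohort]
    right = [s.with_measurements(s.times_yr[:-1], s.diameters_cm[:-1]) for s in cohort]
    return list(cohort), left, right


@dataclass(frozen=True)
class ForecastSplit:
    """Training series plus the held-out future target for one patient."""

    train: PatientSeries
    target_time_yr: float
    target_diameter_cm: float

    def __post_init__(self):
        if self.train.n < 2:
            raise ValueError("forecast training series needs >= 2 measurements")
        if self.train.times_yr[-1] > self.target_time_yr:
            raise ValueError("training times must precede the target")


def make_forecast_splits(
    cohort: list[PatientSeries],
    gap_yr: float = 2.0,
    window_days: float = 150.0,
) -> list[ForecastSplit]:
    """Per-patient train/target splits with an enforced forecast gap.

    Each patient's final measurement is the prediction target. The target
    and any measurement within ``gap_yr`` years before it are censored from
    the training data; the remaining points are then merged with
    :func:`merge_close_measurements` (censor first, then merge). Patients
    with fewer than two training points after merging are dropped.
    """
    splits: list[ForecastSplit] = []
    dropped = 0
    for s in cohort:
        if s.n < 2:
            dropped += 1
            continue
        target_t = float(s.times_yr[-1])
        target_d = float(s.diameters_cm[-1])
        keep = s.times_yr <= target_t - gap_yr
        keep[-1] = False  # the target itself is always censored
        if keep.sum() < 2:
            dropped += 1
            continue
        train = merge_close_measurements(
            s.with_measurements(s.times_yr[keep], s.diameters_cm[keep]),
            window_days=window_days,
        )
        if train.n < 2:
            dropped += 1
            continue
        splits.append(ForecastSplit(train=train, target_time_yr=target_t,
                                    target_diameter_cm=target_d))
    logger.info(
        "make_forecast_splits: %d splits, %d patients dropped", len(splits), dropped
    )
    return splits
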