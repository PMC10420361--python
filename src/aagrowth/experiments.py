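"""Model-evaluation experiments.

Four analyses run over any set of fitted growth models:

* **stability** — refit every model after deleting each patient's earliest
  (left-censored) or latest (right-censored) measurement and summarise the
  per-patient rate changes; a directionally biased model inflates rates
  under left-censoring and deflates them under right-censoring.
* **forecast** — hold out each patient's final measurement (plus a two-year
  guard window), fit on the remainder, and score the predictions with five
  error metrics.
* **risk factors** — screen clinical covariates against clipped growth
  rates with Mann-Whitney U (categorical) or Spearman rank (numeric) tests,
  plus each covariate's association with size and age at detection.
* **baseline** — per-model median rate and the correlation between rate and
  diameter at detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from .cohort import PatientSeries
from .models import EstimationError, GrowthModel, clip_negative_rates
from .preprocess import ForecastSplit, make_censored_datasets, make_forecast_splits

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityResult",
    "ForecastResult",
    "RiskFactorResult",
    "BaselineResult",
    "run_stability",
    "run_forecast",
    "run_risk_factors",
    "characterize_baseline",
]

# |delta| beyond this (mm/yr) counts as an extreme change: 1 cm/yr
_EXTREME_DELTA_MM = 10.0


@dataclass(frozen=True)
class StabilityResult:
    per_patient: pd.DataFrame  # patient_id, model, rate_full/left/right, deltas
    summary: pd.DataFrame      # one row per model


@dataclass(frozen=True)
class ForecastResult:
    per_patient: pd.DataFrame  # patient_id, model, predicted, actual, raw error
    metrics: pd.DataFrame      # one row per model: the five error metrics


@dataclass(frozen=True)
class RiskFactorResult:
    growth_assoc: pd.DataFrame     # (variable, model) growth-rate associations
    detection_assoc: pd.DataFrame  # variable vs size/age at detection
    n_tests: int


@dataclass(frozen=True)
class BaselineResult:
    summary: pd.DataFrame   # per model: median rate, Spearman R vs detection size
    by_size_group: pd.DataFrame


def _rates_by_patient(model: GrowthModel, clipped: bool = True) -> dict:
    col = "rate_clipped_mm_per_yr" if clipped else "rate_mm_per_yr"
    return dict(zip(model.rates_["patient_id"], model.rates_[col]))


def run_stability(cohort: list[PatientSeries], models: list[GrowthModel],
                  clipped: bool = True) -> StabilityResult:
    """Censoring-stability experiment.

    ``cohort`` must already be merged and filtered to >= 3 measurements per
    patient. Every model is fitted to the full, left-censored and
    right-censored datasets; deltas are rate_censored - rate_full per
    patient (clipped rates by default, matching the downstream-analysis
    convention). The summary reports, per model, the mean/median/IQR of
    each delta, the fraction of |delta| > 1 cm/yr, an asymmetry statistic
    mean(d_left) + mean(d_right) (0 under direction-symmetric error), and a
    Mann-Whitney comparison of the d_left and -d_right distributions.
    """
    full, left, right = make_censored_datasets(cohort)
    rows = []
    summaries = []
    for template in models:
        fits = {}
        for name, data in (("full", full), ("left", left), ("right", right)):
            fits[name] = clone(template).fit(data)
        r_full = _rates_by_patient(fits["full"], clipped)
        r_left = _rates_by_patient(fits["left"], clipped)
        r_right = _rates_by_patient(fits["right"], clipped)
        model_name = template.model_name
        dl, dr = [], []
        for pid in r_full:
            delta_l = r_left[pid] - r_full[pid]
            delta_r = r_right[pid] - r_full[pid]
            dl.append(delta_l)
            dr.append(delta_r)
            rows.append((pid, model_name, r_full[pid], r_left[pid], r_right[pid],
                         delta_l, delta_r))
        dl = np.array(dl)
        dr = np.array(dr)
        both = np.concatenate([dl, dr])
        sym_p = _mannwhitney_p(dl, -dr)
        summaries.append(
            {
                "model": model_name,
                "mean_delta_left": dl.mean(),
                "median_delta_left": np.median(dl),
                "iqr_delta_left": stats.iqr(dl),
                "mean_delta_right": dr.mean(),
                "median_delta_right": np.median(dr),
                "iqr_delta_right": stats.iqr(dr),
                "frac_extreme": float(np.mean(np.abs(both) > _EXTREME_DELTA_MM)),
                "asymmetry": dl.mean() + dr.mean(),
                "symmetry_p": sym_p,
                "n": dl.size,
            }
        )
    per_patient = pd.DataFrame(
        rows, columns=["patient_id", "model", "rate_full", "rate_left",
                       "rate_right", "delta_left", "delta_right"])
    return StabilityResult(per_patient=per_patient, summary=pd.DataFrame(summaries))


def run_forecast(cohort: list[PatientSeries], models: list[GrowthModel],
                 gap_yr: float = 2.0, window_days: float = 150.0,
                 splits: list[ForecastSplit] | None = None) -> ForecastResult:
    """Future-diameter forecasting experiment.

    Builds train/target splits from the raw cohort (unless ``splits`` is
    supplied), fits each model on the pooled training series, predicts each
    patient's diameter at the target time, and reports per model: mean
    squared projection error (cm^2), median and mean absolute projection
    error (cm), mean raw (signed) projection error (cm), and the mean over
    patients of each patient's mean squared residual to the training points
    (cm^2). Raw error = predicted - actual, so a negative mean raw error
    means the model tends to underestimate future size.
    """
    if splits is None:
        splits = make_forecast_splits(cohort, gap_yr=gap_yr, window_days=window_days)
    train_cohort = [sp.train for sp in splits]
    rows = []
    metric_rows = []
    for template in models:
        model = clone(template).fit(train_cohort)
        raw_errors, abs_errors, sq_errors, train_mses = [], [], [], []
        n_failed = 0
        for sp in splits:
            pid = sp.train.patient_id
            try:
                pred = float(model.predict(pid, sp.target_time_yr))
                fitted = np.asarray(model.predict(pid, sp.train.times_yr), float)
            except EstimationError:
                n_failed += 1
                continue
            if not np.isfinite(pred):
                n_failed += 1
                continue
            err = pred - sp.target_diameter_cm
            raw_errors.append(err)
            abs_errors.append(abs(err))
            sq_errors.append(err * err)
            train_mses.append(float(np.mean((fitted - sp.train.diameters_cm) ** 2)))
            rows.append((pid, model.model_name, pred, sp.target_diameter_cm, err))
        if n_failed:
            logger.warning("%s: %d patients excluded from forecast metrics",
                           model.model_name, n_failed)
        metric_rows.append(
            {
                "model": model.model_name,
                "mse": float(np.mean(sq_errors)),
                "median_abs_error": float(np.median(abs_errors)),
                "mean_abs_error": float(np.mean(abs_errors)),
                "mean_raw_error": float(np.mean(raw_errors)),
                "mean_training_mse": float(np.mean(train_mses)),
                "n": len(raw_errors),
            }
        )
    per_patient = pd.DataFrame(
        rows, columns=["patient_id", "model", "predicted_cm", "actual_cm",
                       "raw_error_cm"])
    return ForecastResult(per_patient=per_patient, metrics=pd.DataFrame(metric_rows))


def _mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p; exact for small tie-free groups, 1.0 when all tied."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values tied; Mann-Whitney p reported as 1")
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _spearman(x, y):
    """Spearman R and p over pairwise-complete observations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return np.nan, np.nan, int(mask.sum())
    r, p = stats.spearmanr(x[mask], y[mask])
    return float(r), float(p), int(mask.sum())


def _infer_variable_types(cohort) -> dict:
    types = {}
    for s in cohort:
        for name, val in s.covariates.items():
            if name in types:
                continue
            if isinstance(val, (bool, np.bool_, str)):
                types[name] = "categorical"
            else:
                types[name] = "numeric"
    return types


def run_risk_factors(cohort: list[PatientSeries], rates: pd.DataFrame,
                     variables: dict | None = None) -> RiskFactorResult:
    """Screen covariates for association with growth rate.

    ``rates`` is a concatenated rates table (one row per patient and model)
    whose clipped rates are used throughout. ``variables`` maps covariate
    name to "categorical" or "numeric"; inferred from the covariate values
    when omitted. Categorical variables get two-sided Mann-Whitney U tests
    on the clipped rates between carriers and non-carriers; numeric
    variables get Spearman rank correlations. Each variable is additionally
    tested against diameter at detection and age at detection (the
    detection-window confounder checks). p-values are reported without any
    multiple-comparison adjustment; ``n_tests`` counts the tests run so a
    reader can judge the implied false-positive load. Significant means
    p < 0.05, borderline p < 0.1.
    """
    rates = clip_negative_rates(rates)
    if variables is None:
        variables = _infer_variable_types(cohort)
    cov = {s.patient_id: s.covariates for s in cohort}
    det_size = {s.patient_id: s.detection_diameter_cm for s in cohort}
    det_age = {s.patient_id: s.age_at_detection_yr for s in cohort}

    growth_rows = []
    n_tests = 0
    for model_name, grp in rates.groupby("model", sort=False):
        pid = grp["patient_id"].to_numpy()
        rate = grp["rate_clipped_mm_per_yr"].to_numpy(float)
        for var, kind in variables.items():
            vals = np.array([_cov_value(cov.get(p, {}), var) for p in pid], object)
            if kind == "categorical":
                flags = np.array([bool(v) if v is not None else None for v in vals],
                                 object)
                present = rate[[v is True for v in flags]]
                absent = rate[[v is False for v in flags]]
                if present.size == 0 or absent.size == 0:
                    warnings.warn(f"variable {var}: empty group, skipped")
                    continue
                p = _mannwhitney_p(present, absent)
                n_tests += 1
                growth_rows.append(
                    {
                        "variable": var, "model": model_name, "kind": kind,
                        "mean_present": float(present.mean()),
                        "mean_absent": float(absent.mean()),
                        "difference": float(present.mean() - absent.mean()),
                        "spearman_r": np.nan,
                        "p": p, "n_present": present.size, "n_absent": absent.size,
                        "significant": p < 0.05, "borderline": p < 0.1,
                    }
                )
            else:
                x = np.array([v if v is not None else np.nan for v in vals], float)
                r, p, n = _spearman(x, rate)
                n_tests += 1
                growth_rows.append(
                    {
                        "variable": var, "model": model_name, "kind": kind,
                        "mean_present": np.nan, "mean_absent": np.nan,
                        "difference": np.nan, "spearman_r": r,
                        "p": p, "n_present": n, "n_absent": 0,
                        "significant": bool(p < 0.05) if np.isfinite(p) else False,
                        "borderline": bool(p < 0.1) if np.isfinite(p) else False,
                    }
                )

    det_rows = []
    pids = [s.patient_id for s in cohort]
    for var, kind in variables.items():
        for outcome_name, outcome in (("detection_diameter_cm", det_size),
                                      ("age_at_detection_yr", det_age)):
            y = np.array([outcome[p] if outcome[p] is not None else np.nan
                          for p in pids], float)
            if not np.isfinite(y).any():
                continue
            if kind == "categorical":
                flags = [bool(_cov_value(cov[p], var))
                         if _cov_value(cov[p], var) is not None else None
                         for p in pids]
                present = y[[f is True for f in flags]]
                absent = y[[f is False for f in flags]]
                present = present[np.isfinite(present)]
                absent = absent[np.isfinite(absent)]
                if present.size == 0 or absent.size == 0:
                    continue
                p = _mannwhitney_p(present, absent)
                n_tests += 1
                det_rows.append(
                    {
                        "variable": var, "outcome": outcome_name, "kind": kind,
                        "mean_present": float(present.mean()),
                        "mean_absent": float(absent.mean()),
                        "difference": float(present.mean() - absent.mean()),
                        "spearman_r": np.nan, "p": p,
                    }
                )
            else:
                x = np.array([_cov_value(cov[p], var) if
                              _cov_value(cov[p], var) is not None else np.nan
                              for p in pids], float)
                r, p, _ = _spearman(x, y)
                n_tests += 1
                det_rows.append(
                    {
                        "variable": var, "outcome": outcome_name, "kind": kind,
                        "mean_present": np.nan, "mean_absent": np.nan,
                        "difference": np.nan, "spearman_r": r, "p": p,
                    }
                )
    return RiskFactorResult(
        growth_assoc=pd.DataFrame(growth_rows),
        detection_assoc=pd.DataFrame(det_rows),
        n_tests=n_tests,
    )


def _cov_value(covs: dict, name: str):
    val = covs.get(name)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    return val


_SIZE_BINS = [2.0, 3.0, 3.5, 4.0, 4.5, np.inf]
_SIZE_LABELS = ["<3.0", "3.0-3.4", "3.5-3.9", "4.0-4.4", ">=4.5"]


def characterize_baseline(cohort: list[PatientSeries], rates: pd.DataFrame,
                          clipped: bool = True) -> BaselineResult:
    """Median rate per model and its relation to diameter at detection."""
    rates = clip_negative_rates(rates)
    col = "rate_clipped_mm_per_yr" if clipped else "rate_mm_per_yr"
    det = {s.patient_id: s.detection_diameter_cm for s in cohort}
    rows = []
    binned = []
    for model_name, grp in rates.groupby("model", sort=False):
        r = grp[col].to_numpy(float)
        size = np.array([det[p] for p in grp["patient_id"]], float)
        sp_r, sp_p, n = _spearman(size, r)
        rows.append(
            {
                "model": model_name,
                "median_rate_mm_per_yr": float(np.median(r)),
                "spearman_r_vs_detection_size": sp_r,
                "spearman_p": sp_p,
                "n": n,
            }
        )
        groups = pd.cut(size, _SIZE_BINS, labels=_SIZE_LABELS, right=False)
        for label in _SIZE_LABELS:
            mask = np.asarray(groups == label)
            if mask.any():
                binned.append(
                    {
                        "model": model_name, "size_group": label,
                        "median_rate_mm_per_yr": float(np.median(r[mask])),
                        "n": int(mask.sum()),
                    }
                )
    return BaselineResult(summary=pd.DataFrame(rows),
                          by_size_group=pd.DataFrame(binned))
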