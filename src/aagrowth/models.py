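"""The five growth-rate estimators and rate standardisation.

Models
------
first_last        chord between each patient's first and last measurement
linear_unpooled   per-patient ordinary least squares, diameter on time
exp_unpooled      per-patient nonlinear least squares of d(t) = e^{a(t+b)} + 2,
                  with an automatic linear fallback when the curve fit is
                  infeasible
linear_mixed      hierarchical Bayesian linear model (partial pooling)
exp_mixed         hierarchical Bayesian offset-exponential model

Diameters are in cm; growth rates are reported in mm/yr. Exponential fits
are standardised to a single comparable number — the *benchmark rate* — by
taking the linear rate between the model-implied times at which the curve
crosses 4.0 cm and 4.5 cm, which reduces to 5 a / ln(1.25) mm/yr.

All estimators follow the scikit-learn protocol: construct with
hyperparameters, ``fit`` on a cohort (a list of :class:`PatientSeries` or a
long-format measurement DataFrame), then read the fitted ``rates_`` table or
``predict`` diameters for individual patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator

from . import _mcmc
from .cohort import PatientSeries, read_cohort

__all__ = [
    "EstimationError",
    "LinearFit",
    "ExponentialFit",
    "GrowthEstimate",
    "MixedModelPosterior",
    "benchmark_rate",
    "clip_negative_rates",
    "predict_diameter",
    "fit_first_last",
    "fit_linear_unpooled",
    "fit_exponential_unpooled",
    "fit_linear_mixed",
    "fit_exponential_mixed",
    "FirstLastModel",
    "LinearUnpooledModel",
    "ExponentialUnpooledModel",
    "LinearMixedModel",
    "ExponentialMixedModel",
    "MODEL_REGISTRY",
    "make_models",
]

_LN_125 = math.log(1.25)


class EstimationError(ValueError):
    """A series violates a model's preconditions (too few points, etc.)."""


@dataclass(frozen=True)
class LinearFit:
    intercept_cm: float
    slope_cm_per_yr: float

    def predict(self, t_yr):
        return self.intercept_cm + self.slope_cm_per_yr * np.asarray(t_yr, float)


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of d(t) = e^{a(t+b)} + 2; NaN when the linear fallback is in use."""

    a: float
    b: float
    converged: bool = True
    fallback_linear: LinearFit | None = None

    def predict(self, t_yr):
        if self.fallback_linear is not None:
            return self.fallback_linear.predict(t_yr)
        arg = np.minimum(self.a * (np.asarray(t_yr, float) + self.b), 60.0)
        return np.exp(arg) + 2.0


@dataclass(frozen=True)
class GrowthEstimate:
    patient_id: str
    model_name: str
    rate_mm_per_yr: float
    rate_clipped_mm_per_yr: float
    fallback: bool = False
    converged: bool = True


@dataclass(frozen=True)
class MixedModelPosterior:
    """Posterior summaries of a hierarchical fit.

    ``patient_summary`` has one row per patient (central tendency and sd of
    each per-patient parameter plus its split-R-hat); ``hyper_summary`` has
    one row per population-level parameter. ``draws`` retains the raw
    post-warm-up draws keyed by parameter name, shaped (chain, draw, ...).
    """

    patient_summary: pd.DataFrame
    hyper_summary: pd.DataFrame
    chains: int
    draws_per_chain: int
    warmup: int
    seed: int
    draws: dict | None = None


def benchmark_rate(a: float, b: float = 0.0) -> float:
    """Standardised growth rate (mm/yr) of an offset-exponential fit.

    Computes the times at which the curve crosses 4.0 and 4.5 cm,
    t(d) = ln(d - 2)/a - b, and returns the linear rate between those two
    crossings. Cross-checks the result against the closed form
    5 a / ln(1.25); a = 0 (a flat curve that never crosses) maps to rate 0
    by convention, consistent with downstream clipping.
    """
    if a == 0.0 or not math.isfinite(a):
        return 0.0
    t40 = math.log(4.0 - 2.0) / a - b
    t45 = math.log(4.5 - 2.0) / a - b
    rate = 10.0 * 0.5 / (t45 - t40)
    closed = 5.0 * a / _LN_125
    if not math.isclose(rate, closed, rel_tol=1e-9):
        raise AssertionError(
            f"benchmark-rate cross-check failed: {rate} vs {closed}"
        )
    return rate


def clip_negative_rates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Replace negative rates with zero in ``rate_clipped_mm_per_yr``.

    The raw ``rate_mm_per_yr`` column is preserved for audit.
    """
    out = estimates.copy()
    out["rate_clipped_mm_per_yr"] = np.maximum(out["rate_mm_per_yr"], 0.0)
    return out


def predict_diameter(fit, t_yr):
    """Evaluate a fitted per-patient model at time(s) ``t_yr`` (cm)."""
    if isinstance(fit, (LinearFit, ExponentialFit)):
        return fit.predict(t_yr)
    raise TypeError(f"cannot predict from {type(fit).__name__}")


# ---------------------------------------------------------------------------
# estimators


def _as_cohort(X) -> list[PatientSeries]:
    if isinstance(X, pd.DataFrame):
        return read_cohort(X)
    cohort = list(X)
    if not all(isinstance(s, PatientSeries) for s in cohort):
        raise TypeError("expected a measurement DataFrame or a list of PatientSeries")
    return cohort


def _check_series(s: PatientSeries, min_points: int = 2):
    if s.n < min_points:
        raise EstimationError(
            f"patient {s.patient_id}: {s.n} measurement(s), need >= {min_points}"
        )
    if s.times_yr[-1] == s.times_yr[0]:
        raise EstimationError(f"patient {s.patient_id}: zero time span")


class GrowthModel(BaseEstimator):
    """Shared fit/predict scaffolding for the five estimators."""

    model_name: str = ""

    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        for s in cohort:
            _check_series(s)
        self._cohort_ids_ = [s.patient_id for s in cohort]
        records = self._fit_cohort(cohort)
        self.rates_ = clip_negative_rates(
            pd.DataFrame(
                records,
                columns=["patient_id", "model", "rate_mm_per_yr",
                         "rate_clipped_mm_per_yr", "fallback", "converged"],
            )
        )
        self.n_patients_ = len(cohort)
        return self

    def _fit_cohort(self, cohort):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, patient_id: str, t_yr):
        """Predicted diameter (cm) for one fitted patient at time(s) t_yr."""
        if not hasattr(self, "fits_"):
            raise EstimationError("model is not fitted")
        try:
            fit = self.fits_[patient_id]
        except KeyError:
            raise EstimationError(f"patient {patient_id} was not in the fitted cohort")
        return predict_diameter(fit, t_yr)

    def estimates(self) -> list[GrowthEstimate]:
        return [
            GrowthEstimate(
                patient_id=r.patient_id,
                model_name=r.model,
                rate_mm_per_yr=r.rate_mm_per_yr,
                rate_clipped_mm_per_yr=r.rate_clipped_mm_per_yr,
                fallback=bool(r.fallback),
                converged=bool(r.converged),
            )
            for r in self.rates_.itertuples()
        ]


class FirstLastModel(GrowthModel):
    """Chord between the first and last measurement; interior points ignored."""

    model_name = "first_last"

    def _fit_cohort(self, cohort):
        self.fits_ = {}
        records = []
        for s in cohort:
            t0, t1 = s.times_yr[0], s.times_yr[-1]
            d0, d1 = s.diameters_cm[0], s.diameters_cm[-1]
            slope = (d1 - d0) / (t1 - t0)
            self.fits_[s.patient_id] = LinearFit(d0 - slope * t0, slope)
            rate = 10.0 * slope
            records.append((s.patient_id, self.model_name, rate, max(rate, 0.0),
                            False, True))
        return records


class LinearUnpooledModel(GrowthModel):
    """Per-patient ordinary least squares of diameter on time."""

    model_name = "linear_unpooled"

    def _fit_cohort(self, cohort):
        self.fits_ = {}
        records = []
        for s in cohort:
            fit = _ols_fit(s)
            self.fits_[s.patient_id] = fit
            rate = 10.0 * fit.slope_cm_per_yr
            records.append((s.patient_id, self.model_name, rate, max(rate, 0.0),
                            False, True))
        return records


def _ols_fit(s: PatientSeries) -> LinearFit:
    t, d = s.times_yr, s.diameters_cm
    if np.ptp(t) == 0:
        raise EstimationError(f"patient {s.patient_id}: degenerate time design")
    slope, intercept = np.polyfit(t, d, 1)
    return LinearFit(float(intercept), float(slope))


def _exp_curve(t, a, b):
    return np.exp(np.minimum(a * (t + b), 60.0)) + 2.0


def _loglinear_init(t, d):
    """Starting (a, b) from regressing ln(d - 2) on t; None when infeasible."""
    mask = d > 2.05
    if mask.sum() < 2 or np.ptp(t[mask]) == 0:
        return None
    slope, intercept = np.polyfit(t[mask], np.log(d[mask] - 2.0), 1)
    if slope <= 0:
        return None
    return float(slope), float(intercept / slope)


class ExponentialUnpooledModel(GrowthModel):
    """Per-patient nonlinear least squares of the offset-exponential curve.

    The optimiser is started from a log-linear regression of ln(d - 2) on t.
    When that initialisation is infeasible (fewer than two points above the
    2 cm asymptote, or a non-positive log-slope — typically a shrinking or
    flat series), or when the optimiser fails or returns non-finite
    parameters, the patient falls back to the unpooled linear fit and the
    linear rate, flagged in the output.
    """

    model_name = "exp_unpooled"

    def _fit_cohort(self, cohort):
        self.fits_ = {}
        records = []
        for s in cohort:
            fit = self._fit_one(s)
            self.fits_[s.patient_id] = fit
            if fit.fallback_linear is not None:
                rate = 10.0 * fit.fallback_linear.slope_cm_per_yr
            else:
                rate = benchmark_rate(fit.a, fit.b)
            records.append((s.patient_id, self.model_name, rate, max(rate, 0.0),
                            fit.fallback_linear is not None, fit.converged))
        return records

    @staticmethod
    def _fit_one(s: PatientSeries) -> ExponentialFit:
        t, d = s.times_yr, s.diameters_cm
        init = _loglinear_init(t, d)
        linear = _ols_fit(s)
        if init is None:
            return ExponentialFit(math.nan, math.nan, False, linear)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_exp_curve, t, d, p0=init, maxfev=10000)
        except RuntimeError:
            return ExponentialFit(math.nan, math.nan, False, linear)
        a, b = popt
        if not (math.isfinite(a) and math.isfinite(b)):
            return ExponentialFit(math.nan, math.nan, False, linear)
        return ExponentialFit(float(a), float(b), True, None)


def _concat_cohort(cohort):
    t = np.concatenate([s.times_yr for s in cohort])
    d = np.concatenate([s.diameters_cm for s in cohort])
    idx = np.concatenate([np.full(s.n, i, dtype=np.intp)
                          for i, s in enumerate(cohort)])
    return t, d, idx


def _split_rhat(arr: np.ndarray) -> np.ndarray:
    """Split-R-hat per trailing dimension of a (chain, draw, n) array."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(arr)
        rh = az.rhat(ds)
    return np.atleast_1d(np.asarray(rh.to_array()).squeeze())


def _central(draws: np.ndarray, how: str) -> np.ndarray:
    """Central tendency across the pooled post-warm-up draws of all chains."""
    flat = draws.reshape(-1, draws.shape[-1]) if draws.ndim == 3 else draws.reshape(-1)
    if how == "median":
        return np.median(flat, axis=0)
    if how == "mean":
        return np.mean(flat, axis=0)
    raise ValueError(f"unknown central tendency {how!r}")


class _MixedModel(GrowthModel):
    """Common machinery for the two hierarchical Bayesian estimators."""

    def __init__(self, chains=4, warmup=1000, draws=1000, seed=0,
                 center="median", rhat_threshold=1.1, store_draws=True):
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.center = center
        self.rhat_threshold = rhat_threshold
        self.store_draws = store_draws

    # names of the two per-patient parameters in the sampler output
    _param_keys: tuple = ()
    _hyper_keys: tuple = ()

    def _sample(self, cohort):  # pragma: no cover - abstract
        raise NotImplementedError

    def _fit_cohort(self, cohort):
        raw = self._sample(cohort)
        p1, p2 = self._param_keys
        c1 = _central(raw[p1], self.center)
        c2 = _central(raw[p2], self.center)
        if self.chains > 1:
            rh1 = _split_rhat(raw[p1])
            rh2 = _split_rhat(raw[p2])
        else:
            rh1 = np.full(len(cohort), np.nan)
            rh2 = np.full(len(cohort), np.nan)
        converged = ~((rh1 > self.rhat_threshold) | (rh2 > self.rhat_threshold))

        self.patient_params_ = {p1: c1, p2: c2}
        summary = pd.DataFrame(
            {
                "patient_id": [s.patient_id for s in cohort],
                p1: c1,
                f"{p1}_sd": raw[p1].reshape(-1, len(cohort)).std(axis=0),
                f"rhat_{p1}": rh1,
                p2: c2,
                f"{p2}_sd": raw[p2].reshape(-1, len(cohort)).std(axis=0),
                f"rhat_{p2}": rh2,
                "converged": converged,
            }
        )
        hyper = pd.DataFrame(
            {
                "param": list(self._hyper_keys),
                "central": [float(_central(raw[k], self.center))
                            for k in self._hyper_keys],
                "sd": [float(raw[k].std()) for k in self._hyper_keys],
            }
        )
        self.posterior_ = MixedModelPosterior(
            patient_summary=summary,
            hyper_summary=hyper,
            chains=self.chains,
            draws_per_chain=self.draws,
            warmup=self.warmup,
            seed=self.seed,
            draws=raw if self.store_draws else None,
        )
        return self._records_from_params(cohort, c1, c2, converged)


class LinearMixedModel(_MixedModel):
    """Hierarchical Bayesian linear growth model.

    d_ij = alpha_i + beta_i t_ij + eps with (alpha_i, beta_i) partially
    pooled across patients. Per-patient rates come from the central tendency
    (default: posterior median of the pooled chains) of beta_i; estimates
    are reported for every patient regardless of convergence, with a
    split-R-hat flag recorded per patient.
    """

    model_name = "linear_mixed"
    _param_keys = ("alpha", "beta")
    _hyper_keys = ("mu_alpha", "mu_beta", "tau_alpha", "tau_beta", "sigma")

    def _sample(self, cohort):
        t, d, idx = _concat_cohort(cohort)
        return _mcmc.sample_linear_hierarchy(
            t, d, idx, len(cohort), chains=self.chains, warmup=self.warmup,
            draws=self.draws, seed=self.seed)

    def _records_from_params(self, cohort, alpha, beta, converged):
        self.fits_ = {}
        records = []
        for i, s in enumerate(cohort):
            self.fits_[s.patient_id] = LinearFit(float(alpha[i]), float(beta[i]))
            rate = 10.0 * float(beta[i])
            records.append((s.patient_id, self.model_name, rate, max(rate, 0.0),
                            False, bool(converged[i])))
        return records


class ExponentialMixedModel(_MixedModel):
    """Hierarchical Bayesian offset-exponential growth model.

    d_ij = e^{a_i (t_ij + b_i)} + 2 + eps, with log a_i and b_i partially
    pooled, so a_i > 0 structurally and the benchmark rate is always
    defined. The likelihood is on the raw cm scale (diameters below 2 cm
    from noise are fine). Patients whose unpooled curve fit fails still
    receive finite (a_i, b_i) via pooling.
    """

    model_name = "exp_mixed"
    _param_keys = ("la", "b")
    _hyper_keys = ("mu_la", "mu_b", "tau_la", "tau_b", "sigma")

    def _sample(self, cohort):
        t, d, idx = _concat_cohort(cohort)
        init_la, init_b = _mixed_exp_init(cohort)
        return _mcmc.sample_exponential_hierarchy(
            t, d, idx, len(cohort), init_la, init_b, chains=self.chains,
            warmup=self.warmup, draws=self.draws, seed=self.seed)

    def _records_from_params(self, cohort, la, b, converged):
        self.fits_ = {}
        records = []
        for i, s in enumerate(cohort):
            a_i = float(np.exp(la[i]))
            fit = ExponentialFit(a_i, float(b[i]), bool(converged[i]), None)
            self.fits_[s.patient_id] = fit
            rate = benchmark_rate(a_i, float(b[i]))
            records.append((s.patient_id, self.model_name, rate, max(rate, 0.0),
                            False, bool(converged[i])))
        return records


def _mixed_exp_init(cohort):
    """Per-patient (log a, b) starting values for the hierarchical sampler."""
    init_la = np.empty(len(cohort))
    init_b = np.empty(len(cohort))
    for i, s in enumerate(cohort):
        init = _loglinear_init(s.times_yr, s.diameters_cm)
        if init is not None and -6.0 < math.log(init[0]) < 1.0:
            init_la[i] = math.log(init[0])
            init_b[i] = init[1]
        else:
            a0 = math.exp(-2.5)
            init_la[i] = -2.5
            d0 = max(float(s.diameters_cm[0]) - 2.0, 0.05)
            init_b[i] = math.log(d0) / a0 - float(s.times_yr[0])
    return init_la, init_b


# ---------------------------------------------------------------------------
# functional wrappers over the estimators


def fit_first_last(series: PatientSeries) -> GrowthEstimate:
    """First-last growth rate: total growth / total time observed (mm/yr)."""
    return FirstLastModel().fit([series]).estimates()[0]


def fit_linear_unpooled(series: PatientSeries):
    """Unpooled OLS fit; returns (LinearFit, GrowthEstimate)."""
    m = LinearUnpooledModel().fit([series])
    return m.fits_[series.patient_id], m.estimates()[0]


def fit_exponential_unpooled(series: PatientSeries):
    """Unpooled offset-exponential fit; returns (ExponentialFit, GrowthEstimate)."""
    m = ExponentialUnpooledModel().fit([series])
    return m.fits_[series.patient_id], m.estimates()[0]


def fit_linear_mixed(cohort, **kwargs):
    """Hierarchical linear fit; returns (MixedModelPosterior, [GrowthEstimate])."""
    m = LinearMixedModel(**kwargs).fit(cohort)
    return m.posterior_, m.estimates()


def fit_exponential_mixed(cohort, **kwargs):
    """Hierarchical offset-exponential fit; returns (MixedModelPosterior, [GrowthEstimate])."""
    m = ExponentialMixedModel(**kwargs).fit(cohort)
    return m.posterior_, m.estimates()


MODEL_REGISTRY = {
    "first_last": FirstLastModel,
    "linear_unpooled": LinearUnpooledModel,
    "exp_unpooled": ExponentialUnpooledModel,
    "linear_mixed": LinearMixedModel,
    "exp_mixed": ExponentialMixedModel,
}


def make_models(names=None, **mixed_kwargs) -> list[GrowthModel]:
    """Instantiate models by name; ``mixed_kwargs`` go to the Bayesian models."""
    if names is None:
        names = list(MODEL_REGISTRY)
    models = []
    for name in names:
        cls = MODEL_REGISTRY[name]
        if issubclass(cls, _MixedModel):
            models.append(cls(**mixed_kwargs))
        else:
            models.append(cls())
    return models
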