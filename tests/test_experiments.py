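"""Stability, forecasting, risk-factor and baseline experiment mechanics."""

import numpy as np
import pandas as pd
import pytest

from aagrowth import (
    FirstLastModel,
    LinearUnpooledModel,
    characterize_baseline,
    fit_first_last,
    run_forecast,
    run_risk_factors,
    run_stability,
)
from tests.conftest import make_series


def _linear_cohort(n=12, slope=0.2, n_points=4):
    cohort = []
    for i in range(n):
        t = np.arange(n_points, dtype=float)
        d = 3.0 + (slope + 0.01 * i) * t
        cohort.append(make_series(f"p{i}", t, d))
    return cohort


class TestStability:
    def test_noiseless_linear_cohort_has_zero_deltas(self):
        cohort = _linear_cohort()
        res = run_stability(cohort, [FirstLastModel(), LinearUnpooledModel()])
        assert np.allclose(res.per_patient["delta_left"], 0.0, atol=1e-9)
        assert np.allclose(res.per_patient["delta_right"], 0.0, atol=1e-9)
        assert np.allclose(res.summary["asymmetry"], 0.0, atol=1e-9)

    def test_first_last_ignores_interior_point_removal(self):
        # guard on the delta plumbing: the censoring protocol removes
        # endpoints only, so removing an interior point must not change a
        # first-last rate at all
        s = make_series("p", [0.0, 1.0, 2.0, 3.0], [3.0, 3.7, 3.1, 3.9])
        full = fit_first_last(s)
        pruned = fit_first_last(
            make_series("p", [0.0, 1.0, 3.0], [3.0, 3.7, 3.9])
        )
        assert pruned.rate_mm_per_yr == full.rate_mm_per_yr

    def test_summary_has_one_row_per_model(self):
        cohort = _linear_cohort()
        res = run_stability(cohort, [FirstLastModel()])
        assert list(res.summary["model"]) == ["first_last"]
        assert res.summary["n"].iloc[0] == len(cohort)


class TestForecast:
    def test_metrics_match_hand_arithmetic(self):
        # chords predict 4.0 and 3.5; targets are 3.8 and 3.7, so the raw
        # errors are [0.2, -0.2]
        cohort = [
            make_series("a", [0.0, 2.0, 5.0], [3.0, 3.4, 3.8]),
            make_series("b", [0.0, 1.0, 4.0], [3.1, 3.2, 3.7]),
        ]
        res = run_forecast(cohort, [FirstLastModel()])
        errs = res.per_patient.sort_values("patient_id")["raw_error_cm"].to_numpy()
        np.testing.assert_allclose(errs, [0.2, -0.2], atol=1e-12)
        row = res.metrics.iloc[0]
        assert row["mean_raw_error"] == pytest.approx(0.0, abs=1e-12)
        assert row["mean_abs_error"] == pytest.approx(0.2)
        assert row["median_abs_error"] == pytest.approx(0.2)
        assert row["mse"] == pytest.approx(0.04)
        assert row["mean_training_mse"] == pytest.approx(0.0, abs=1e-20)

    def test_perfect_predictions_zero_all_metrics(self):
        cohort = [
            make_series(f"p{i}", [0.0, 1.0, 5.0],
                        3.0 + 0.1 * (i + 1) * np.array([0.0, 1.0, 5.0]))
            for i in range(3)
        ]
        res = run_forecast(cohort, [FirstLastModel(), LinearUnpooledModel()])
        for col in ("mse", "median_abs_error", "mean_abs_error",
                    "mean_raw_error", "mean_training_mse"):
            np.testing.assert_allclose(res.metrics[col], 0.0, atol=1e-12)

    def test_error_magnitude_inequalities_hold(self):
        rng = np.random.default_rng(5)
        cohort = []
        for i in range(25):
            t = np.concatenate([[0.0, 1.0], [rng.uniform(3.5, 6.0)]])
            d = 3.0 + 0.2 * t + rng.normal(0, 0.2, 3)
            cohort.append(make_series(f"p{i}", t, np.maximum(d, 0.5)))
        res = run_forecast(cohort, [LinearUnpooledModel()])
        row = res.metrics.iloc[0]
        assert row["mean_abs_error"] >= abs(row["mean_raw_error"])
        assert row["mse"] >= row["mean_raw_error"] ** 2
        assert row["mse"] >= 0


class TestRiskFactors:
    def _cohort_with_rates(self):
        cohort = []
        rates = []
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        for i, r in enumerate(vals):
            cov = {"exposed": i >= 3, "score": float(i)}
            cohort.append(
                make_series(f"p{i}", [0.0, 1.0], [3.0, 3.0 + r / 10.0],
                            covariates=cov, age_at_detection_yr=70.0 + i)
            )
            rates.append({"patient_id": f"p{i}", "model": "first_last",
                          "rate_mm_per_yr": r})
        return cohort, pd.DataFrame(rates)

    def test_separated_groups_get_exact_small_sample_p(self):
        cohort, rates = self._cohort_with_rates()
        res = run_risk_factors(cohort, rates)
        row = res.growth_assoc.set_index("variable").loc["exposed"]
        # groups {4,5,6} vs {1,2,3}: exact two-sided Mann-Whitney p = 0.1
        assert row["p"] == pytest.approx(0.1)
        assert row["mean_present"] == pytest.approx(5.0)
        assert row["mean_absent"] == pytest.approx(2.0)
        # p sits exactly on the 0.1 boundary: neither significant nor borderline
        assert not row["significant"] and not row["borderline"]

    def test_monotone_numeric_covariate_has_unit_spearman_r(self):
        cohort, rates = self._cohort_with_rates()
        res = run_risk_factors(cohort, rates)
        row = res.growth_assoc.set_index("variable").loc["score"]
        assert row["spearman_r"] == pytest.approx(1.0)

    def test_detection_associations_are_reported(self):
        cohort, rates = self._cohort_with_rates()
        res = run_risk_factors(cohort, rates)
        outcomes = set(zip(res.detection_assoc["variable"],
                           res.detection_assoc["outcome"]))
        assert ("exposed", "detection_diameter_cm") in outcomes
        assert ("exposed", "age_at_detection_yr") in outcomes
        assert ("score", "detection_diameter_cm") in outcomes

    def test_all_tied_rates_give_p_one_with_warning(self):
        cohort, rates = self._cohort_with_rates()
        rates["rate_mm_per_yr"] = 2.0
        with pytest.warns(UserWarning, match="tied"):
            res = run_risk_factors(cohort, rates,
                                   variables={"exposed": "categorical"})
        assert res.growth_assoc["p"].iloc[0] == 1.0

    def test_empty_group_is_skipped_with_warning(self):
        cohort, rates = self._cohort_with_rates()
        for s in cohort:
            s.covariates["exposed"] = True
        with pytest.warns(UserWarning, match="empty group"):
            res = run_risk_factors(cohort, rates,
                                   variables={"exposed": "categorical"})
        assert res.growth_assoc.empty


class TestBaseline:
    def test_median_of_small_rate_set(self):
        cohort = [make_series(f"p{i}", [0.0, 1.0], [3.0 + 0.1 * i, 3.5])
                  for i in range(5)]
        rates = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(5)],
             "model": ["m"] * 5,
             "rate_mm_per_yr": [1.0, 2.0, 3.0, 4.0, 5.0]}
        )
        res = characterize_baseline(cohort, rates)
        assert res.summary["median_rate_mm_per_yr"].iloc[0] == pytest.approx(3.0)
        assert res.by_size_group["n"].sum() == 5
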