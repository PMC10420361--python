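"""Measurement merging, filters, censored datasets and forecast splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aagrowth import (
    filter_min_measurements,
    make_censored_datasets,
    make_forecast_splits,
    merge_close_measurements,
    read_cohort,
)
from aagrowth.cohort import DAYS_PER_YEAR, CohortFormatError, CohortValidationError

DAY = 1.0 / DAYS_PER_YEAR


def test_two_points_within_window_average_to_one(series_factory):
    s = series_factory("p", [0.0, 100 * DAY], [3.0, 3.2])
    m = merge_close_measurements(s)
    assert m.n == 1
    assert m.times_yr[0] == pytest.approx(50 * DAY)
    assert m.diameters_cm[0] == pytest.approx(3.1)


def test_points_separated_by_window_are_kept(series_factory):
    s = series_factory("p", [0.0, 200 * DAY], [3.0, 3.4])
    m = merge_close_measurements(s)
    assert m.n == 2
    np.testing.assert_array_equal(m.diameters_cm, s.diameters_cm)


def test_greedy_cluster_then_next_point_kept(series_factory):
    # cluster {0, 100} -> (50, 3.1); 260 is 160 days past the previous cluster
    # member (100), >= 150, so it stays separate
    s = series_factory("p", [0.0, 100 * DAY, 260 * DAY], [3.0, 3.2, 3.4])
    m = merge_close_measurements(s)
    assert m.n == 2
    assert m.times_yr[0] == pytest.approx(50 * DAY)
    assert m.diameters_cm[0] == pytest.approx(3.1)
    assert m.times_yr[1] == pytest.approx(260 * DAY)


def test_gap_is_measured_from_the_previous_member_not_the_cluster_mean(
    series_factory,
):
    # 240 is 140 days after member 100 (absorbed), even though it is 190 days
    # after the eventual cluster mean of 50
    s = series_factory("p", [0.0, 100 * DAY, 240 * DAY], [3.0, 3.2, 3.4])
    m = merge_close_measurements(s)
    assert m.n == 1
    assert m.diameters_cm[0] == pytest.approx(3.2)


def test_chained_close_points_form_one_cluster(series_factory):
    # consecutive gaps of 100 days chain into a single cluster even though
    # the endpoints are 200 days apart
    s = series_factory("p", [0.0, 100 * DAY, 200 * DAY], [3.0, 3.2, 3.4])
    m = merge_close_measurements(s)
    assert m.n == 1
    assert m.diameters_cm[0] == pytest.approx(3.2)


def reference_merge(times, diams, window_yr=150 * DAY):
    """Independent restatement of the greedy merge rule (oracle)."""
    clusters = [[0]]
    for i in range(1, len(times)):
        if times[i] - times[clusters[-1][-1]] < window_yr:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    out_t = [float(np.mean([times[i] for i in c])) for c in clusters]
    out_d = [float(np.mean([diams[i] for i in c])) for c in clusters]
    sizes = [len(c) for c in clusters]
    return out_t, out_d, sizes


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    gaps=st.lists(st.floats(1.0, 400.0), min_size=1, max_size=10),
    d0=st.floats(2.5, 5.0),
)
def test_merge_is_idempotent_and_mass_preserving(gaps, d0):
    times = np.concatenate([[0.0], np.cumsum(gaps)]) * DAY
    rng = np.random.default_rng(0)
    diams = d0 + np.abs(rng.normal(0, 0.3, times.size)).cumsum()
    from aagrowth import PatientSeries

    s = PatientSeries("p", times, diams)
    m1 = merge_close_measurements(s)
    m2 = merge_close_measurements(m1)
    np.testing.assert_array_equal(m1.times_yr, m2.times_yr)
    np.testing.assert_array_equal(m1.diameters_cm, m2.diameters_cm)
    # consecutive output gaps respect the window
    if m1.n > 1:
        assert np.all(np.diff(m1.times_yr) >= 150 * DAY - 1e-12)
    ref_t, ref_d, sizes = reference_merge(s.times_yr, s.diameters_cm)
    np.testing.assert_allclose(m1.times_yr, ref_t, rtol=1e-12)
    # cluster-size-weighted diameter sum is conserved
    mass = float(np.dot(m1.diameters_cm, sizes))
    assert mass == pytest.approx(s.diameters_cm.sum(), rel=1e-9)


def test_filter_min_measurements_counts(series_factory):
    cohort = [
        series_factory("a", [0, 1], [3, 3.1]),
        series_factory("b", [0, 1, 2], [3, 3.1, 3.2]),
        series_factory("c", [0, 1, 2, 3, 4], [3, 3.1, 3.2, 3.3, 3.4]),
        series_factory("d", [0], [3]),
    ]
    assert len(filter_min_measurements(cohort, 2)) == 3
    assert len(filter_min_measurements(cohort, 3)) == 2
    assert filter_min_measurements([], 2) == []
    with pytest.raises(ValueError):
        filter_min_measurements(cohort, 0)


def test_censored_datasets_drop_the_correct_endpoints(series_factory):
    cohort = [series_factory(f"p{i}", [0.0, 1.0, 2.0], [3.0, 3.2, 3.5])
              for i in range(10)]
    full, left, right = make_censored_datasets(cohort)
    assert len(full) == len(left) == len(right) == 10
    for f, l, r in zip(full, left, right):
        np.testing.assert_array_equal(l.times_yr, [1.0, 2.0])
        np.testing.assert_array_equal(r.times_yr, [0.0, 1.0])
        assert l.n == r.n == f.n - 1


def test_censoring_requires_three_measurements(series_factory):
    with pytest.raises(ValueError, match="filter"):
        make_censored_datasets([series_factory("p", [0, 1], [3, 3.1])])


def test_forecast_split_keeps_points_up_to_the_gap(series_factory):
    s = series_factory("p", [0.0, 1.0, 2.0, 5.0], [3.0, 3.1, 3.2, 3.8])
    (split,) = make_forecast_splits([s])
    assert split.target_time_yr == 5.0
    assert split.target_diameter_cm == 3.8
    np.testing.assert_array_equal(split.train.times_yr, [0.0, 1.0, 2.0])


def test_forecast_split_drops_patient_left_with_one_point(series_factory):
    s = series_factory("p", [0.0, 4.5, 5.0], [3.0, 3.6, 3.8])
    assert make_forecast_splits([s]) == []


def test_forecast_split_censors_then_merges(series_factory):
    s = series_factory("p", [0.0, 0.3, 3.0, 6.0], [3.0, 3.1, 3.4, 4.0])
    (split,) = make_forecast_splits([s])
    # candidates {0, 0.3, 3}; 0 and 0.3 merge (109.6 days apart)
    assert split.train.n == 2
    assert split.train.times_yr[0] == pytest.approx(0.15)
    assert split.train.diameters_cm[0] == pytest.approx(3.05)
    assert split.train.times_yr[1] == pytest.approx(3.0)


def test_forecast_split_gap_invariant(rng):
    from aagrowth import CohortConfig, generate_cohort

    cohort = generate_cohort(CohortConfig(n_patients=80, seed=17))
    for split in make_forecast_splits(cohort):
        assert split.train.times_yr.max() <= split.target_time_yr - 2.0 + 1e-12


# --- reading tables ---------------------------------------------------------


def test_read_cohort_groups_and_zeroes_time():
    meas = pd.DataFrame(
        {
            "patient_id": ["a", "a", "a", "b", "b"],
            "time_yr": [1.0, 2.0, 4.0, 0.5, 1.5],
            "diameter_cm": [3.0, 3.2, 3.6, 4.0, 4.1],
        }
    )
    cohort = read_cohort(meas)
    assert [s.patient_id for s in cohort] == ["a", "b"]
    assert [s.n for s in cohort] == [3, 2]
    np.testing.assert_allclose(cohort[0].times_yr, [0.0, 1.0, 3.0])
    np.testing.assert_allclose(cohort[1].times_yr, [0.0, 1.0])


def test_read_cohort_converts_dates_to_years():
    meas = pd.DataFrame(
        {
            "patient_id": ["a", "a"],
            "date": ["2015-01-01", "2016-01-01"],
            "diameter_cm": [3.0, 3.3],
        }
    )
    (s,) = read_cohort(meas)
    assert s.times_yr[1] == pytest.approx(1.0, abs=1.5 / DAYS_PER_YEAR)


def test_read_cohort_rejects_bad_diameter_naming_the_row():
    meas = pd.DataFrame(
        {"patient_id": ["a", "b"], "time_yr": [0.0, 0.0], "diameter_cm": [3.0, -1.0]}
    )
    with pytest.raises(CohortValidationError, match="b"):
        read_cohort(meas)


def test_read_cohort_requires_columns():
    with pytest.raises(CohortFormatError):
        read_cohort(pd.DataFrame({"patient_id": ["a"], "diameter_cm": [3.0]}))
    with pytest.raises(CohortFormatError):
        read_cohort(pd.DataFrame({"patient_id": ["a"], "time_yr": [0.0]}))


def test_read_cohort_warns_on_unmatched_covariates(caplog):
    meas = pd.DataFrame(
        {"patient_id": ["a", "a"], "time_yr": [0.0, 1.0], "diameter_cm": [3.0, 3.2]}
    )
    cov = pd.DataFrame({"patient_id": ["a", "zzz"], "diabetes": [True, False]})
    import logging

    with caplog.at_level(logging.WARNING):
        (s,) = read_cohort(meas, cov)
    assert s.covariates == {"diabetes": True}
    assert "zzz" in caplog.text
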