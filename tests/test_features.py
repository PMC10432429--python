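"""Feature engineering: wear time, HR statistics, temporal variants,
clinical features and full-matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import postopfit as pf
from postopfit.features import (CLINICAL_DEMOGRAPHIC_FEATURES,
                                FEATURE_COLUMNS, VARIANT_SUFFIXES)
from postopfit.synthetic_cohort import MINUTES_PER_DAY, MinutePanel


# ---------------------------------------------------------------------------
# wear time
# ---------------------------------------------------------------------------

def _day(worn_minutes):
    hr = np.full(MINUTES_PER_DAY, np.nan)
    hr[list(worn_minutes)] = 80.0
    return hr


def test_wear_time_zero_when_hr_recorded_but_zero():
    hr = np.zeros(MINUTES_PER_DAY)  # recorded zeros = not worn, but data
    hours, any_data = pf.compute_wear_time(hr)
    assert hours == 0.0 and any_data is True


def test_wear_time_counts_only_waking_window():
    # 600 worn minutes entirely inside 06:00-24:00
    hours, _ = pf.compute_wear_time(_day(range(600, 1200)))
    assert hours == 10.0
    # 120 of the 600 fall before 06:00 and do not count
    hours, _ = pf.compute_wear_time(_day(list(range(240, 360))
                                         + list(range(600, 1080))))
    assert hours == 8.0


def test_wear_time_no_data_day():
    hours, any_data = pf.compute_wear_time(np.full(MINUTES_PER_DAY, np.nan))
    assert hours == 0.0 and any_data is False


@given(st.sets(st.integers(0, MINUTES_PER_DAY - 1), max_size=60),
       st.integers(0, MINUTES_PER_DAY - 1))
@settings(max_examples=50, derandomize=True)
def test_wear_monotone_in_worn_minutes(worn, extra):
    base, _ = pf.compute_wear_time(_day(worn))
    more, _ = pf.compute_wear_time(_day(set(worn) | {extra}))
    assert more >= base


# ---------------------------------------------------------------------------
# HR statistics
# ---------------------------------------------------------------------------

def test_hr_stats_two_values():
    hr = np.full(MINUTES_PER_DAY, np.nan)
    hr[100], hr[200] = 80.0, 100.0
    s = pf.daily_hr_stats(hr)
    assert s["hr_mean"] == 90.0 and s["hr_min"] == 80.0
    assert s["hr_max"] == 100.0
    assert s["hr_sd"] == pytest.approx(14.142, abs=1e-3)


def test_hr_stats_constant_and_not_worn():
    s = pf.daily_hr_stats(np.full(MINUTES_PER_DAY, 75.0))
    assert s["hr_mean"] == s["hr_min"] == s["hr_max"] == 75.0
    assert s["hr_sd"] == 0.0
    for v in pf.daily_hr_stats(np.zeros(MINUTES_PER_DAY)).values():
        assert np.isnan(v)  # a day of recorded zeros is a not-worn day


def test_hr_stats_single_worn_minute_has_no_sd():
    hr = np.full(MINUTES_PER_DAY, np.nan)
    hr[500] = 90.0
    s = pf.daily_hr_stats(hr)
    assert s["hr_mean"] == 90.0 and np.isnan(s["hr_sd"])


# ---------------------------------------------------------------------------
# temporal variants
# ---------------------------------------------------------------------------

def brute_force_variants(values: dict, pod: int) -> dict:
    """Independent rule-by-rule oracle over explicit loops."""
    out = {s: np.nan for s in VARIANT_SUFFIXES}
    v = values.get(pod, np.nan)
    if np.isnan(v):
        return out
    prev = [values[p] for p in sorted(values) if p < pod
            and not np.isnan(values[p])]
    if pod - 1 in values and not np.isnan(values[pod - 1]):
        out["delta"] = v - values[pod - 1]
    window = [values[p] for p in (pod - 3, pod - 2, pod - 1)
              if p in values and not np.isnan(values[p])]
    if window:
        roll3 = sum(window) / len(window)
        out["roll3_diff"] = v - roll3
        if roll3 != 0:
            out["roll3_pct"] = 100.0 * (v - roll3) / roll3
    if prev:
        out["max_diff"] = v - max(prev)
        out["min_diff"] = v - min(prev)
    return out


def test_variants_worked_example():
    s = pd.Series([10.0, 20.0, 30.0, 40.0], index=[1, 2, 3, 4])
    row = pf.temporal_variants(s).loc[4]
    assert row["delta"] == 10 and row["roll3_diff"] == 20
    assert row["roll3_pct"] == 100 and row["max_diff"] == 10
    assert row["min_diff"] == 30


def test_variants_constant_series_all_zero():
    s = pd.Series(5.0, index=range(1, 8))
    out = pf.temporal_variants(s)
    assert (out.loc[2:].to_numpy() == 0).all()


def test_variants_first_day_all_missing():
    out = pf.temporal_variants(pd.Series([10.0], index=[1]))
    assert out.loc[1].isna().all()


@given(st.lists(st.one_of(st.none(),
                          st.floats(-1e3, 1e3, allow_nan=False)),
                min_size=1, max_size=12))
@settings(max_examples=200, derandomize=True)
def test_variants_match_brute_force_oracle(raw):
    values = {i + 1: (np.nan if x is None else x) for i, x in enumerate(raw)}
    series = pd.Series(values)
    result = pf.temporal_variants(series)
    for pod in series.index:
        expected = brute_force_variants(values, pod)
        for suffix in VARIANT_SUFFIXES:
            got = result.at[pod, suffix]
            want = expected[suffix]
            assert (np.isnan(got) and np.isnan(want)) or \
                got == pytest.approx(want, rel=1e-9, abs=1e-9), \
                (pod, suffix, got, want)


# ---------------------------------------------------------------------------
# clinical features
# ---------------------------------------------------------------------------

EMPTY_EVENTS = pd.DataFrame(columns=["patient_id", "pod", "category",
                                     "clavien_grade", "nsqip"])


def test_clinical_no_events():
    out = pf.clinical_features({"length_of_stay_days": 2.6}, EMPTY_EVENTS, 5)
    assert out["days_post_surgery"] == 5
    assert out["days_post_symptom"] == 5      # no-prior-event upper bound
    assert out["n_past_symptoms"] == 0 and out["past_symptom"] == 0
    assert out["discharged"] == 1.0           # ceil(2.6) = 3 <= 5


def test_clinical_with_prior_symptom():
    events = pd.DataFrame([("A", 3, "symptom", "I", False)],
                          columns=EMPTY_EVENTS.columns)
    out = pf.clinical_features({"length_of_stay_days": 2.0}, events, 6)
    assert out["days_post_symptom"] == 3
    assert out["past_symptom"] == 1 and out["n_past_symptoms"] == 1
    assert out["days_post_complication"] == 6  # none occurred


def test_clinical_not_yet_discharged_and_bad_pod():
    out = pf.clinical_features({"length_of_stay_days": 4.0}, EMPTY_EVENTS, 1)
    assert out["discharged"] == 0.0
    with pytest.raises(ValueError):
        pf.clinical_features({"length_of_stay_days": 4.0}, EMPTY_EVENTS, 0)


# ---------------------------------------------------------------------------
# full matrix assembly
# ---------------------------------------------------------------------------

def _tiny_cohort(drop_pod=None, no_sleep_pod=None):
    """One patient, 21 deterministic days (optionally one dropped, one
    without sleep fields)."""
    pods = [p for p in range(1, 22) if p != drop_pod]
    hr = np.full((len(pods), MINUTES_PER_DAY), np.nan, dtype=np.float32)
    steps = np.zeros((len(pods), MINUTES_PER_DAY), dtype=np.int32)
    hr[:, 480:1200] = 85.0
    steps[:, 480:1200] = 5
    patients = pd.DataFrame([{
        "patient_id": "A", "group": "complicated", "age_years": 10.0,
        "sex": "female", "race_ethnicity": "hispanic_latinx",
        "weight_kg": 35.0, "height_cm": 140.0, "device": "inspire_hr",
        "length_of_stay_days": 3.0, "monitoring_days": 21,
        "surgery_date": pd.Timestamp("2021-03-01")}])
    rows = []
    for i, pod in enumerate(pods):
        row = {"patient_id": "A", "pod": pod,
               "total_steps": float(steps[i].sum()),
               "total_distance_km": 2.0, "calories": 1500.0,
               "resting_hr_bpm": 80.0}
        if pod != no_sleep_pod:
            row.update({"total_min_asleep": 480.0, "total_min_in_bed": 500.0,
                        "total_min_restless": 20.0, "sleep_records": 1.0})
        rows.append(row)
    summaries = pd.DataFrame(rows)
    panel = MinutePanel(np.array(["A"] * len(pods), dtype=object),
                        np.array(pods), hr, steps)
    return pf.Cohort(patients=patients, events=EMPTY_EVENTS.copy(),
                     minutes=panel, daily_summaries=summaries)


def test_full_data_patient_has_fixed_column_set():
    features, wear = pf.build_feature_matrix(_tiny_cohort())
    assert len(features) == 21
    assert list(features.columns) == ["patient_id", "pod"] + FEATURE_COLUMNS
    assert len(wear) == 21
    assert set(CLINICAL_DEMOGRAPHIC_FEATURES) < set(features.columns)


def test_day_without_sleep_retained_with_missing_sleep():
    features, _ = pf.build_feature_matrix(_tiny_cohort(no_sleep_pod=10))
    row = features[features["pod"] == 10].iloc[0]
    assert np.isnan(row["total_min_asleep"])
    assert row["total_steps"] > 0  # activity features still present


def test_dropped_day_omitted_and_rolling_window_skips_it():
    features, _ = pf.build_feature_matrix(_tiny_cohort(drop_pod=8))
    assert len(features) == 20
    assert 8 not in set(features["pod"])
    # POD 9's rolling stats come from PODs 6-7 (POD 8 absent): constant
    # series, so the rolling-difference is exactly 0, not missing
    row = features[features["pod"] == 9].iloc[0]
    assert row["total_steps_roll3_diff"] == 0.0


def test_unknown_stream_patient_rejected():
    cohort = _tiny_cohort()
    cohort.minutes.patient_id[:] = "GHOST"
    with pytest.raises(ValueError, match="GHOST"):
        pf.build_feature_matrix(cohort)


def test_one_hot_race_completeness(small_tables):
    features = small_tables["features"]
    race_cols = [c for c in features.columns if c.startswith("race_")]
    assert sorted(features[race_cols].sum(axis=1).unique()) == [1.0]


def test_column_set_identical_across_patients(small_tables):
    features = small_tables["features"]
    # every row carries the same columns by construction; check no column is
    # all-missing for one patient but the set remains canonical
    assert list(features.columns) == ["patient_id", "pod"] + FEATURE_COLUMNS
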