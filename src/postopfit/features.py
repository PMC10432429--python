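"""Per-day feature engineering from minute streams and daily summaries.

Builds the per patient-day feature vectors used by the recovery classifier:
activity and sleep summary fields passed through from the device's daily
export, heart-rate statistics recomputed from the minute stream over worn
minutes only, demographics (one-hot categorical encoding), clinical-course
features derived from the event log, and five temporal-variant operators
applied to seven flagged features:

* ``delta``      — difference from the previous day,
* ``roll3_diff`` — difference from the 3-day rolling average of the
  preceding days (current day excluded),
* ``roll3_pct``  — percent change from that rolling average,
* ``max_diff``   — difference from the maximum of all previous days,
* ``min_diff``   — difference from the minimum of all previous days.

Wear time is inferred from heart rate: a minute counts as worn iff an HR
sample is recorded and nonzero; compliance is measured as worn hours within
potential waking hours (06:00-24:00). Missingness is a value throughout, not
an error: a quantity with no qualifying prior data is simply absent (NaN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import RACE_LEVELS, Cohort

WAKING_START_MINUTE = 6 * 60   # 06:00
WAKING_END_MINUTE = 24 * 60    # midnight (exclusive)

ACTIVITY_FEATURES = [
    "total_steps", "total_distance_km", "logged_activities_distance_km",
    "very_active_distance_km", "moderately_active_distance_km",
    "lightly_active_distance_km", "sedentary_active_distance_km",
    "very_active_min", "fairly_active_min", "lightly_active_min",
    "sedentary_min", "calories", "calories_bmr", "marginal_calories",
]
HEART_RATE_FEATURES = ["resting_hr_bpm", "hr_mean", "hr_sd", "hr_min",
                       "hr_max"]
SLEEP_FEATURES = ["total_min_asleep", "total_min_in_bed",
                  "total_min_restless", "sleep_records"]
DEMOGRAPHIC_FEATURES = (["age_years", "weight_kg", "height_cm", "sex_female"]
                        + [f"race_{r}" for r in RACE_LEVELS])
CLINICAL_FEATURES = [
    "days_post_surgery", "days_post_symptom", "days_post_complication",
    "past_symptom", "past_complication", "n_past_symptoms",
    "n_past_complications", "discharged",
]

#: features that receive the five temporal variants
FLAGGED_FEATURES = [
    "total_steps", "total_distance_km", "calories", "resting_hr_bpm",
    "total_min_asleep", "total_min_in_bed", "total_min_restless",
]
VARIANT_SUFFIXES = ["delta", "roll3_diff", "roll3_pct", "max_diff",
                    "min_diff"]
VARIANT_FEATURES = [f"{f}_{s}" for f in FLAGGED_FEATURES
                    for s in VARIANT_SUFFIXES]

#: canonical column order; greedy correlation pruning scans in this order
FEATURE_COLUMNS = (ACTIVITY_FEATURES + HEART_RATE_FEATURES + SLEEP_FEATURES
                   + DEMOGRAPHIC_FEATURES + CLINICAL_FEATURES
                   + VARIANT_FEATURES)

#: sensitivity analysis 1 ("no wearable data") feature subset
CLINICAL_DEMOGRAPHIC_FEATURES = DEMOGRAPHIC_FEATURES + CLINICAL_FEATURES


@dataclass(frozen=True)
class WearRecord:
    patient_id: str
    pod: int
    wear_hours_waking: float
    any_data: bool


def compute_wear_time(hr: np.ndarray, steps: np.ndarray | None = None
                      ) -> tuple[float, bool]:
    """Wear hours within waking hours (06:00-24:00) for one patient-day.

    A minute is worn iff its HR sample is recorded and positive (zero or
    absent HR means "device not worn"). ``any_data`` is True iff the day has
    any recorded sample at all, worn or not.
    """
    hr = np.asarray(hr, dtype=float)
    worn = np.nan_to_num(hr) > 0
    waking = np.zeros(len(hr), dtype=bool)
    waking[WAKING_START_MINUTE:WAKING_END_MINUTE] = True
    wear_hours = float((worn & waking).sum()) / 60.0
    any_data = bool((~np.isnan(hr)).any()
                    or (steps is not None and np.any(np.asarray(steps) > 0)))
    return wear_hours, any_data


def daily_hr_stats(hr: np.ndarray) -> dict:
    """Mean / sample SD / min / max of HR over worn minutes of one day.

    Zero worn minutes => all four statistics missing (NaN), never zero;
    a single worn minute yields a defined mean but a missing SD (n-1
    denominator).
    """
    hr = np.asarray(hr, dtype=float)
    worn = hr[np.nan_to_num(hr) > 0]
    if worn.size == 0:
        return {k: np.nan for k in ("hr_mean", "hr_sd", "hr_min", "hr_max")}
    return {
        "hr_mean": float(worn.mean()),
        "hr_sd": float(worn.std(ddof=1)) if worn.size > 1 else np.nan,
        "hr_min": float(worn.min()),
        "hr_max": float(worn.max()),
    }


def temporal_variants(series: pd.Series) -> pd.DataFrame:
    """The five temporal variants of one flagged feature.

    ``series`` is indexed by POD (missing entries allowed, as NaN or as
    absent index entries). The 3-day rolling average covers calendar PODs
    pod-3..pod-1 (current day excluded), using whichever of those are
    present. Any undefined quantity — no qualifying prior data, a zero
    rolling average for the percent variant, or a missing current value —
    is NaN.
    """
    pods = sorted(series.index)
    if not pods:
        return pd.DataFrame(columns=VARIANT_SUFFIXES, dtype=float,
                            index=pd.Index([], name="pod"))
    lo, hi = pods[0], pods[-1]
    v = series.reindex(range(lo, hi + 1)).to_numpy(dtype=float)
    n = len(v)
    def _shift(k: int) -> np.ndarray:
        return np.concatenate([np.full(min(k, n), np.nan),
                               v[:max(n - k, 0)]])

    # direct 3-term window sum (PODs pod-3..pod-1, ascending) — avoids the
    # cancellation a cumulative-sum formulation suffers at mixed scales
    window = np.stack([_shift(3), _shift(2), _shift(1)])
    cnt3 = (~np.isnan(window)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        roll3 = np.where(cnt3 > 0,
                         np.nansum(window, axis=0) / np.maximum(cnt3, 1),
                         np.nan)
        delta = v - _shift(1)
        roll3_diff = v - roll3
        roll3_pct = np.where(roll3 == 0, np.nan, 100.0 * roll3_diff / roll3)
    # fmax/fmin.accumulate skip NaN, so gaps do not break the running extrema
    prev_max = np.concatenate([[np.nan], np.fmax.accumulate(v)[:-1]])
    prev_min = np.concatenate([[np.nan], np.fmin.accumulate(v)[:-1]])
    out = pd.DataFrame(
        {"delta": delta, "roll3_diff": roll3_diff, "roll3_pct": roll3_pct,
         "max_diff": v - prev_max, "min_diff": v - prev_min},
        index=pd.Index(range(lo, hi + 1), name="pod"))
    return out.loc[pods]


def clinical_features(patient: pd.Series | dict, events: pd.DataFrame,
                      pod: int) -> dict:
    """Clinical-course features for one patient-day.

    Only events strictly before ``pod`` contribute; a category with no prior
    event uses ``pod`` itself (days since surgery) as the no-prior-event
    upper bound for the days-since features. Discharge is derived from the
    ceiling of length of stay unless the roster supplies an explicit
    ``discharge_pod``.
    """
    if pod < 1:
        raise ValueError(f"pod must be >= 1, got {pod}")
    prior = events[events["pod"] < pod] if len(events) else events
    out = {"days_post_surgery": float(pod)}
    for cat, stem in (("symptom", "symptom"), ("complication",
                                               "complication")):
        sub = prior[prior["category"] == cat] if len(prior) else prior
        n = int(len(sub))
        last = int(sub["pod"].max()) if n else None
        out[f"days_post_{stem}"] = float(pod - last) if last else float(pod)
        out[f"past_{stem}"] = float(n > 0)
        out[f"n_past_{stem}s"] = float(n)
    discharge_pod = patient.get("discharge_pod") if hasattr(patient, "get") \
        else None
    if discharge_pod is None or (isinstance(discharge_pod, float)
                                 and math.isnan(discharge_pod)):
        discharge_pod = math.ceil(float(patient["length_of_stay_days"]))
    out["discharged"] = float(pod >= discharge_pod)
    return out


def _demographics_row(patient: pd.Series) -> dict:
    row = {
        "age_years": float(patient["age_years"]),
        "weight_kg": float(patient["weight_kg"]),
        "height_cm": float(patient["height_cm"]),
        "sex_female": float(patient["sex"] == "female"),
    }
    for r in RACE_LEVELS:
        row[f"race_{r}"] = float(patient["race_ethnicity"] == r)
    return row


def build_feature_matrix(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the full feature table and the wear table for a cohort.

    Returns ``(features, wear)``: one row per patient-day with any recorded
    data (days with no data at all are omitted), with the fixed canonical
    column set; and a wear table (patient_id, pod, wear_hours_waking,
    any_data) over the same days.
    """
    patients = cohort.patients
    known = set(patients["patient_id"])
    stream_ids = set(cohort.minutes.patient_id)
    unknown = stream_ids - known
    if unknown:
        raise ValueError(f"patients present in streams but absent from the "
                         f"roster: {sorted(unknown)}")

    panel = cohort.minutes
    hrw = np.where(np.nan_to_num(panel.hr) > 0, panel.hr, np.nan)
    waking = slice(WAKING_START_MINUTE, WAKING_END_MINUTE)
    worn_waking = (np.nan_to_num(panel.hr[:, waking]) > 0).sum(axis=1)
    n_worn = (~np.isnan(hrw)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN day slices
        hr_mean = np.nanmean(hrw, axis=1)
        hr_sd = np.nanstd(hrw, axis=1, ddof=1)
        hr_min = np.nanmin(hrw, axis=1)
        hr_max = np.nanmax(hrw, axis=1)
    hr_sd = np.where(n_worn > 1, hr_sd, np.nan)

    stream = pd.DataFrame({
        "patient_id": panel.patient_id, "pod": panel.pod,
        "hr_mean": hr_mean, "hr_sd": hr_sd, "hr_min": hr_min,
        "hr_max": hr_max,
        "wear_hours_waking": worn_waking / 60.0,
        "any_data": ((~np.isnan(panel.hr)).any(axis=1)
                     | (panel.steps > 0).any(axis=1)),
    })

    from .synthetic_cohort import SUMMARY_FIELDS
    summaries = cohort.daily_summaries.set_index(["patient_id", "pod"])
    summaries = summaries.reindex(columns=SUMMARY_FIELDS)  # absent => NaN
    base = stream.set_index(["patient_id", "pod"]).join(summaries, how="outer")
    # a day present only in the daily summary still counts as having data
    base["any_data"] = base["any_data"].fillna(True).astype(bool)
    base["wear_hours_waking"] = base["wear_hours_waking"].fillna(0.0)
    base = base[base["any_data"]].sort_index()

    wear = base.reset_index()[["patient_id", "pod", "wear_hours_waking",
                               "any_data"]]

    rows = patients.set_index("patient_id")
    demo = pd.DataFrame(
        {pid: _demographics_row(rows.loc[pid]) for pid in rows.index}).T
    feats = base.join(demo, on="patient_id")

    clin_records = []
    events = cohort.events
    for pid, pod in feats.index:
        ev = events[events["patient_id"] == pid] if len(events) else events
        clin_records.append(clinical_features(rows.loc[pid], ev, int(pod)))
    feats = pd.concat(
        [feats, pd.DataFrame(clin_records, index=feats.index)], axis=1)

    patient_frames = []
    for pid, grp in feats.groupby(level="patient_id", sort=False):
        per_pod = grp.droplevel("patient_id")
        cols = []
        for f in FLAGGED_FEATURES:
            var = temporal_variants(per_pod[f].astype(float))
            var.columns = [f"{f}_{s}" for s in VARIANT_SUFFIXES]
            cols.append(var)
        block = pd.concat(cols, axis=1)
        block.index = pd.MultiIndex.from_product(
            [[pid], block.index], names=["patient_id", "pod"])
        patient_frames.append(block)
    if patient_frames:
        feats = feats.join(pd.concat(patient_frames))
    else:
        for c in VARIANT_FEATURES:
            feats[c] = np.nan

    features = feats.reset_index()[["patient_id", "pod"] + FEATURE_COLUMNS]
    features = features.astype({c: float for c in FEATURE_COLUMNS})
    return features, wear
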