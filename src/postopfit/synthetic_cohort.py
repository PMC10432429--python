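"""Synthetic post-appendectomy wearable cohort generator.

Emulates a 21-day postoperative monitoring study of children after
laparoscopic appendectomy: a patient roster (two disease-severity groups,
complicated vs simple appendicitis), sparse postoperative events (abnormal
symptoms / complications graded on the Clavien-Dindo scale), minute-level
heart-rate and step streams with realistic non-wear gaps, and per-day
activity/sleep summaries of the kind consumer devices export.

The generator's defaults encode the study conditions the downstream analysis
assumes: 85 complicated / 76 simple patients, expected event counts of 41 and
10, mean daily wear of 12.8 h / 12.3 h, device mix 69/85 and 43/76 Inspire HR,
and a Clavien grade mix matching the observed frequencies. The 1-2 days before
each event carry a configurable activity suppression and heart-rate elevation
(the early-warning signal the classifier is meant to recover); the magnitude
of that perturbation is a free parameter, not a literature value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
GROUPS = ("complicated", "simple")
CLAVIEN_GRADES = ("I", "II", "III", "IV", "V")
RACE_LEVELS = ("nh_white", "hispanic_latinx", "african_american", "other")
DEVICES = ("inspire_hr", "inspire_2")

#: base calendar date assigned to POD 0 of the first patient; purely
#: presentational (timestamps in the CSV dialect are ISO-8601 local).
BASE_SURGERY_DATE = pd.Timestamp("2021-03-01")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config field {name!r}: {msg}")


@dataclass(frozen=True)
class PreEventEffect:
    """Perturbation applied on the 1-2 days preceding each event.

    step_suppression: fraction of minute steps removed (0 = no signal).
    hr_elevation_bpm: beats/min added to every worn-minute HR sample.
    """

    step_suppression: float = 0.5
    hr_elevation_bpm: float = 15.0

    def validate(self) -> None:
        _check(0.0 <= self.step_suppression <= 1.0, "step_suppression",
               "must be a fraction in [0, 1]")
        _check(self.hr_elevation_bpm >= 0.0, "hr_elevation_bpm",
               "must be non-negative")


@dataclass(frozen=True)
class GroupParams:
    """Per-severity-group generator parameters."""

    n_patients: int
    event_rate_per_patient: float
    grade_probs: dict = field(default_factory=dict)
    wear_hours_mean: float = 12.0
    wear_hours_sd: float = 6.0
    los_mean_days: float = 2.0
    los_sd_days: float = 1.0
    inspire_hr_frac: float = 0.7
    female_frac: float = 0.5
    race_probs: dict = field(default_factory=dict)
    # logistic recovery ramp of expected daily steps: midpoint POD and scale
    recovery_t50_pod: float = 7.0
    recovery_scale_days: float = 2.5

    def validate(self, name: str) -> None:
        _check(self.n_patients >= 0, f"{name}.n_patients", "must be >= 0")
        _check(self.event_rate_per_patient >= 0.0,
               f"{name}.event_rate_per_patient", "must be >= 0")
        _check(all(g in CLAVIEN_GRADES for g in self.grade_probs),
               f"{name}.grade_probs", "keys must be Clavien grades I-V")
        for pname, probs in (("grade_probs", self.grade_probs),
                             ("race_probs", self.race_probs)):
            if probs:
                total = sum(probs.values())
                _check(abs(total - 1.0) < 1e-6, f"{name}.{pname}",
                       f"probabilities must sum to 1 (got {total:.4f})")
        _check(0.0 <= self.inspire_hr_frac <= 1.0, f"{name}.inspire_hr_frac",
               "must be a fraction in [0, 1]")
        _check(self.wear_hours_mean > 0, f"{name}.wear_hours_mean",
               "must be positive")


def _norm(d: dict) -> dict:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def default_complicated() -> GroupParams:
    # observed frequencies: 41 events among 85 patients; grades 22/14/5;
    # LOS 4.0 +/- 2.6 d; wear 12.8 +/- 6.0 h; 69/85 on the Inspire HR
    return GroupParams(
        n_patients=85,
        event_rate_per_patient=41 / 85,
        grade_probs={"I": 22 / 41, "II": 14 / 41, "III": 5 / 41},
        wear_hours_mean=12.8, wear_hours_sd=6.0,
        los_mean_days=4.0, los_sd_days=2.6,
        inspire_hr_frac=69 / 85,
        female_frac=44 / 85,
        race_probs=_norm({"nh_white": 19, "hispanic_latinx": 53,
                          "african_american": 7, "other": 4}),
        recovery_t50_pod=9.0, recovery_scale_days=3.0,
    )


def default_simple() -> GroupParams:
    return GroupParams(
        n_patients=76,
        event_rate_per_patient=10 / 76,
        grade_probs={"I": 9 / 10, "III": 1 / 10},
        wear_hours_mean=12.3, wear_hours_sd=6.3,
        los_mean_days=0.9, los_sd_days=0.7,
        inspire_hr_frac=43 / 76,
        female_frac=34 / 76,
        race_probs=_norm({"nh_white": 22, "hispanic_latinx": 39,
                          "african_american": 7, "other": 3}),
        recovery_t50_pod=5.0, recovery_scale_days=2.0,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration; ``seed`` fixed => bit-identical output."""

    complicated: GroupParams = field(default_factory=default_complicated)
    simple: GroupParams = field(default_factory=default_simple)
    monitoring_days: int = 21
    pre_event_effect: PreEventEffect = field(default_factory=PreEventEffect)
    seed: int = 0

    # recovery model: expected steps ramp from nadir_frac * plateau to plateau
    plateau_steps_mean: float = 9000.0
    plateau_steps_cv: float = 0.25
    nadir_frac: float = 0.2
    daily_step_noise_cv: float = 0.25

    # minute-level structure
    active_minute_frac: float = 0.15
    # event timing: None = uniform over the monitoring window (keeps day
    # labels independent of the day-level features when no pre-event signal
    # is injected); a number gives truncated-geometric timing with that mean
    event_pod_mean: float | None = None
    day_dropout_prob: float = 0.03        # whole day with no data at all
    sleep_missing_prob: float = 0.10      # summary rows lacking sleep fields

    # NSQIP designation probability by Clavien grade (NSQIP => complication)
    nsqip_prob_by_grade: dict = field(default_factory=lambda: {
        "I": 0.0, "II": 0.6, "III": 1.0, "IV": 1.0, "V": 1.0})

    # daily-summary ("device firmware") parameters
    very_active_steps_per_min: float = 67.0
    fairly_active_steps_per_min: float = 30.0
    lightly_active_steps_per_min: float = 1.0
    sleep_minutes_mean: float = 510.0
    sleep_minutes_sd: float = 45.0
    restless_minutes_mean: float = 35.0
    restless_minutes_sd: float = 12.0

    def validate(self) -> None:
        _check(self.monitoring_days >= 1, "monitoring_days", "must be >= 1")
        _check(0.0 <= self.day_dropout_prob < 1.0, "day_dropout_prob",
               "must be in [0, 1)")
        _check(0.0 <= self.sleep_missing_prob < 1.0, "sleep_missing_prob",
               "must be in [0, 1)")
        _check(self.nadir_frac > 0 and self.nadir_frac <= 1.0, "nadir_frac",
               "must be in (0, 1]")
        self.pre_event_effect.validate()
        self.complicated.validate("complicated")
        self.simple.validate("simple")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass
class MinutePanel:
    """Minute streams for recorded patient-days, one row per patient-day.

    ``hr`` is float with NaN meaning "no HR sample recorded that minute";
    an explicit 0 also means not worn (a recorded zero). ``steps`` are
    non-negative integer counts per minute. Days with no data at all have no
    row in the panel.
    """

    patient_id: np.ndarray   # (n_days,) object
    pod: np.ndarray          # (n_days,) int
    hr: np.ndarray           # (n_days, 1440) float32, NaN = absent
    steps: np.ndarray        # (n_days, 1440) int32

    def __len__(self) -> int:
        return len(self.pod)

    def day(self, patient_id: str, pod: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the (hr, steps) minute vectors for one patient-day."""
        mask = (self.patient_id == patient_id) & (self.pod == pod)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no recorded data for {patient_id} POD {pod}")
        return self.hr[idx[0]], self.steps[idx[0]]

    def subset(self, row_mask: np.ndarray) -> "MinutePanel":
        return MinutePanel(self.patient_id[row_mask], self.pod[row_mask],
                           self.hr[row_mask], self.steps[row_mask])


@dataclass
class Cohort:
    """A generated (or loaded) cohort: roster, events, streams, summaries."""

    patients: pd.DataFrame
    events: pd.DataFrame
    minutes: MinutePanel
    daily_summaries: pd.DataFrame
    monitoring_days: int = 21


SUMMARY_FIELDS = [
    "total_steps", "total_distance_km", "logged_activities_distance_km",
    "very_active_distance_km", "moderately_active_distance_km",
    "lightly_active_distance_km", "sedentary_active_distance_km",
    "very_active_min", "fairly_active_min", "lightly_active_min",
    "sedentary_min", "calories", "calories_bmr", "marginal_calories",
    "resting_hr_bpm", "total_min_asleep", "total_min_in_bed",
    "total_min_restless", "sleep_records",
]

PATIENT_COLUMNS = [
    "patient_id", "group", "age_years", "sex", "race_ethnicity", "weight_kg",
    "height_cm", "device", "length_of_stay_days", "monitoring_days",
    "surgery_date",
]

EVENT_COLUMNS = ["patient_id", "pod", "category", "clavien_grade", "nsqip"]


# ---------------------------------------------------------------------------
# patient roster and event log
# ---------------------------------------------------------------------------

def _draw_patients(group: str, params: GroupParams, config: CohortConfig,
                   rng: np.random.Generator, start_index: int) -> pd.DataFrame:
    n = params.n_patients
    age = np.clip(rng.normal(10.4, 3.6, n), 3.0, 17.0)
    sex = np.where(rng.random(n) < params.female_frac, "female", "male")
    race_levels = list(params.race_probs or
                       {r: 1 / len(RACE_LEVELS) for r in RACE_LEVELS})
    race_p = np.array([ (params.race_probs or {}).get(r, 1 / len(race_levels))
                        for r in race_levels])
    race = rng.choice(race_levels, size=n, p=race_p / race_p.sum())
    # CDC-growth-curve flavored size from age, with individual spread
    height = 80.0 + 5.5 * age + rng.normal(0, 6.0, n)
    weight = np.maximum(2.0 + 0.00042 * height ** 2.2 + rng.normal(0, 4.0, n),
                        10.0)
    device = np.where(rng.random(n) < params.inspire_hr_frac,
                      "inspire_hr", "inspire_2")
    los = np.maximum(rng.normal(params.los_mean_days, params.los_sd_days, n),
                     0.2)
    ids = [f"{group[0].upper()}{start_index + i:03d}" for i in range(n)]
    surgery = [BASE_SURGERY_DATE + pd.Timedelta(days=int(i % 90))
               for i in range(start_index, start_index + n)]
    return pd.DataFrame({
        "patient_id": ids, "group": group,
        "age_years": np.round(age, 1), "sex": sex, "race_ethnicity": race,
        "weight_kg": np.round(weight, 1), "height_cm": np.round(height, 1),
        "device": device, "length_of_stay_days": np.round(los, 1),
        "monitoring_days": config.monitoring_days, "surgery_date": surgery,
    })


def _draw_events(patients: pd.DataFrame, params: GroupParams,
                 config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sparse per-patient events: Poisson counts, early-skewed timing."""
    m = config.monitoring_days
    pods = np.arange(1, m + 1)
    if config.event_pod_mean is None:
        w = np.full(m, 1.0 / m)
    else:  # optional early-skewed (truncated geometric) timing
        w = np.exp(-(pods - 1) / config.event_pod_mean)
        w /= w.sum()
    grades = list(params.grade_probs) or ["I"]
    gp = np.array([params.grade_probs.get(g, 1.0) for g in grades])
    gp = gp / gp.sum()
    rows = []
    for pid in patients["patient_id"]:
        k = min(rng.poisson(params.event_rate_per_patient), m)
        if k == 0:
            continue
        event_pods = np.sort(rng.choice(pods, size=k, replace=False, p=w))
        for pod in event_pods:
            grade = str(rng.choice(grades, p=gp))
            nsqip = bool(rng.random() <
                         config.nsqip_prob_by_grade.get(grade, 0.0))
            rows.append((pid, int(pod), "complication" if nsqip else "symptom",
                         grade, nsqip))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# minute streams
# ---------------------------------------------------------------------------

def _wear_mask(rng: np.random.Generator, wear_hours: float) -> np.ndarray:
    """Boolean worn mask for one day: contiguous overnight non-wear plus
    random daytime gaps; wear is concentrated in waking hours."""
    worn = np.zeros(MINUTES_PER_DAY, dtype=bool)
    wear_min = int(round(wear_hours * 60))
    if wear_min <= 0:
        return worn
    start = int(np.clip(rng.normal(7 * 60, 45), 5 * 60, 10 * 60))
    end = min(start + wear_min, MINUTES_PER_DAY)
    worn[start:end] = True
    deficit = wear_min - (end - start)
    if deficit > 0:  # spill into the early-morning block
        worn[max(0, start - deficit):start] = True
    # carve 0-2 daytime gaps, then pad the evening edge to restore the total
    for _ in range(rng.poisson(1.0)):
        gap_len = int(rng.integers(10, 60))
        gap_start = int(rng.integers(start, max(start + 1, end - gap_len)))
        worn[gap_start:gap_start + gap_len] = False
        pad_end = min(end + gap_len, MINUTES_PER_DAY)
        worn[end:pad_end] = True
        end = pad_end
    return worn


def _simulate_patient_days(patient: pd.Series, params: GroupParams,
                           config: CohortConfig,
                           rng: np.random.Generator):
    """Minute HR/steps for PODs 1..monitoring_days of one patient.

    Returns (pods, hr (d,1440) float32, steps (d,1440) int32) for recorded
    days only (dropout days omitted).
    """
    m = config.monitoring_days
    plateau = config.plateau_steps_mean * rng.lognormal(
        0.0, config.plateau_steps_cv)
    hr_base = float(np.clip(118.0 - 2.2 * patient["age_years"]
                            + rng.normal(0, 5), 55.0, 130.0))
    pods, hr_rows, step_rows = [], [], []
    for pod in range(1, m + 1):
        if rng.random() < config.day_dropout_prob:
            continue
        ramp = 1.0 / (1.0 + np.exp(-(pod - params.recovery_t50_pod)
                                   / params.recovery_scale_days))
        expected = plateau * (config.nadir_frac
                              + (1 - config.nadir_frac) * ramp)
        expected *= rng.lognormal(0.0, config.daily_step_noise_cv)
        wear_hours = float(np.clip(
            rng.normal(params.wear_hours_mean, params.wear_hours_sd),
            2.0, 17.5))
        worn = _wear_mask(rng, wear_hours)
        n_worn = int(worn.sum())
        steps = np.zeros(MINUTES_PER_DAY, dtype=np.int32)
        if n_worn:
            active = worn & (rng.random(MINUTES_PER_DAY)
                             < config.active_minute_frac)
            n_active = int(active.sum())
            if n_active:
                lam = min(expected / n_active, 130.0)
                steps[active] = rng.poisson(lam, n_active)
        hr = np.full(MINUTES_PER_DAY, np.nan, dtype=np.float32)
        if n_worn:
            hr_vals = (hr_base + 0.30 * steps[worn]
                       + rng.normal(0, 4.0, n_worn))
            hr[worn] = np.maximum(np.round(hr_vals), 40.0)
        pods.append(pod)
        hr_rows.append(hr)
        step_rows.append(steps)
    if not pods:
        shape = (0, MINUTES_PER_DAY)
        return (np.array([], dtype=int),
                np.empty(shape, np.float32), np.empty(shape, np.int32))
    return (np.array(pods), np.stack(hr_rows), np.stack(step_rows))


def inject_event_signal(panel: MinutePanel, event: pd.Series | dict,
                        effect: PreEventEffect,
                        monitoring_days: int = 21) -> MinutePanel:
    """Perturb the 1-2 days preceding one event, in place, returning the panel.

    Minute steps on PODs ``event.pod - 2`` and ``event.pod - 1`` (those that
    exist and are >= 1) are scaled by ``1 - step_suppression``; worn-minute HR
    is offset by ``hr_elevation_bpm``. All other days untouched. An event on
    POD 1 has no prior monitored days, so the stream is returned unchanged.
    """
    pod = int(event["pod"])
    if not 1 <= pod <= monitoring_days:
        raise ValueError(f"event POD {pod} outside monitoring window "
                         f"1..{monitoring_days}")
    pid = event["patient_id"]
    target = ((panel.patient_id == pid)
              & np.isin(panel.pod, [pod - 2, pod - 1]) & (panel.pod >= 1))
    for i in np.flatnonzero(target):
        panel.steps[i] = np.round(
            panel.steps[i] * (1.0 - effect.step_suppression)).astype(np.int32)
        worn = np.nan_to_num(panel.hr[i]) > 0
        panel.hr[i, worn] += effect.hr_elevation_bpm
    return panel


# ---------------------------------------------------------------------------
# daily summaries (stand-in for the device's proprietary daily algorithms)
# ---------------------------------------------------------------------------

def summarize_generator_day(hr: np.ndarray, steps: np.ndarray,
                            patient: pd.Series | dict, config: CohortConfig,
                            rng: np.random.Generator,
                            include_sleep: bool = True) -> dict:
    """Daily summary fields recomputed from one day's minute stream.

    total_steps is the exact sum of minute steps; intensity minutes partition
    the worn minutes by step-rate thresholds; distances use a height-scaled
    stride; energy is BMR plus a per-step increment; sleep comes from the
    generator's sleep model (or is absent when ``include_sleep`` is False).
    """
    if len(hr) > MINUTES_PER_DAY:
        raise ValueError("stream-day longer than one calendar day")
    worn = np.nan_to_num(hr) > 0
    total_steps = int(steps.sum())
    stride_km = float(patient["height_cm"]) * 0.414 / 100.0 / 1000.0
    very = worn & (steps >= config.very_active_steps_per_min)
    fairly = worn & ~very & (steps >= config.fairly_active_steps_per_min)
    lightly = (worn & ~very & ~fairly
               & (steps >= config.lightly_active_steps_per_min))
    sedentary = worn & ~very & ~fairly & ~lightly
    dist = lambda mask: round(float(steps[mask].sum()) * stride_km, 4)
    bmr = 500.0 + 20.0 * float(patient["weight_kg"])
    marginal = 0.04 * total_steps
    worn_hr = hr[worn]
    resting = (float(np.round(np.quantile(worn_hr, 0.05)))
               if worn.any() else np.nan)
    out = {
        "total_steps": total_steps,
        "total_distance_km": round(total_steps * stride_km, 4),
        "logged_activities_distance_km": 0.0,
        "very_active_distance_km": dist(very),
        "moderately_active_distance_km": dist(fairly),
        "lightly_active_distance_km": dist(lightly),
        "sedentary_active_distance_km": dist(sedentary),
        "very_active_min": int(very.sum()),
        "fairly_active_min": int(fairly.sum()),
        "lightly_active_min": int(lightly.sum()),
        "sedentary_min": int(sedentary.sum()),
        "calories": round(bmr + marginal, 1),
        "calories_bmr": round(bmr, 1),
        "marginal_calories": round(marginal, 1),
        "resting_hr_bpm": resting,
    }
    if include_sleep:
        asleep = float(np.clip(rng.normal(config.sleep_minutes_mean,
                                          config.sleep_minutes_sd), 300, 700))
        restless = float(max(rng.normal(config.restless_minutes_mean,
                                        config.restless_minutes_sd), 0.0))
        out.update({
            "total_min_asleep": round(asleep),
            "total_min_in_bed": round(asleep + restless
                                      + abs(rng.normal(10, 5))),
            "total_min_restless": round(restless),
            "sleep_records": int(1 + (rng.random() < 0.15)),
        })
    else:
        out.update({k: np.nan for k in ("total_min_asleep", "total_min_in_bed",
                                        "total_min_restless", "sleep_records")})
    return out


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from ``config`` (deterministic in
    ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    frames, group_params = [], {}
    start = 0
    for group in GROUPS:
        params: GroupParams = getattr(config, group)
        group_params[group] = params
        frames.append(_draw_patients(group, params, config, rng, start))
        start += params.n_patients
    nonempty = [f for f in frames if len(f)]
    patients = (pd.concat(nonempty, ignore_index=True) if nonempty
                else pd.DataFrame(columns=PATIENT_COLUMNS))

    event_frames = [
        _draw_events(patients[patients["group"] == g], group_params[g],
                     config, rng) for g in GROUPS]
    event_frames = [f for f in event_frames if len(f)]
    events = (pd.concat(event_frames, ignore_index=True) if event_frames
              else pd.DataFrame(columns=EVENT_COLUMNS))
    if events.empty:
        events = pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {"pod": int, "nsqip": bool})

    pid_all, pod_all, hr_all, steps_all = [], [], [], []
    for _, patient in patients.iterrows():
        pods, hr, steps = _simulate_patient_days(
            patient, group_params[patient["group"]], config, rng)
        pid_all.extend([patient["patient_id"]] * len(pods))
        pod_all.append(pods)
        hr_all.append(hr)
        steps_all.append(steps)
    panel = MinutePanel(
        patient_id=np.array(pid_all, dtype=object),
        pod=np.concatenate(pod_all) if pod_all else np.array([], int),
        hr=np.concatenate(hr_all) if hr_all else
        np.empty((0, MINUTES_PER_DAY), np.float32),
        steps=np.concatenate(steps_all) if steps_all else
        np.empty((0, MINUTES_PER_DAY), np.int32),
    )

    for _, event in events.iterrows():
        inject_event_signal(panel, event, config.pre_event_effect,
                            config.monitoring_days)

    patients_by_id = patients.set_index("patient_id")
    rows = []
    for i in range(len(panel)):
        pid = panel.patient_id[i]
        summary = summarize_generator_day(
            panel.hr[i], panel.steps[i], patients_by_id.loc[pid], config, rng,
            include_sleep=rng.random() >= config.sleep_missing_prob)
        rows.append({"patient_id": pid, "pod": int(panel.pod[i]), **summary})
    daily = pd.DataFrame(rows, columns=["patient_id", "pod"] + SUMMARY_FIELDS)

    return Cohort(patients=patients, events=events, minutes=panel,
                  daily_summaries=daily, monitoring_days=config.monitoring_days)


# ---------------------------------------------------------------------------
# CSV dialect I/O (Fitabase-style, documented in the README)
# ---------------------------------------------------------------------------

def _timestamps(surgery_date: pd.Timestamp, pod: int,
                minutes: np.ndarray) -> pd.Series:
    day0 = surgery_date + pd.Timedelta(days=pod)
    return pd.Series(day0 + pd.to_timedelta(minutes, unit="m")).dt.strftime(
        "%Y-%m-%dT%H:%M")


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the five-table CSV dialect; returns {name: path}.

    minute_hr.csv carries one row per *recorded* HR minute (a recorded zero is
    kept — it encodes "not worn"); minute_steps.csv one row per minute with a
    recorded HR sample or nonzero steps. Days with no data have no rows
    anywhere, including daily_summary.csv.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    patients = cohort.patients.copy()
    patients["surgery_date"] = pd.to_datetime(
        patients["surgery_date"]).dt.strftime("%Y-%m-%dT%H:%M")
    surgery = pd.to_datetime(
        cohort.patients.set_index("patient_id")["surgery_date"])

    def _write(name: str, df: pd.DataFrame):
        path = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")
        paths[name] = path

    _write("patients", patients)
    _write("events", cohort.events)
    _write("daily_summary", cohort.daily_summaries)

    hr_frames, step_frames = [], []
    panel = cohort.minutes
    for i in range(len(panel)):
        pid, pod = panel.patient_id[i], int(panel.pod[i])
        hr, steps = panel.hr[i], panel.steps[i]
        rec = ~np.isnan(hr)
        mins = np.flatnonzero(rec)
        ts = _timestamps(surgery[pid], pod, mins)
        hr_frames.append(pd.DataFrame(
            {"patient_id": pid, "timestamp": ts,
             "hr_bpm": hr[mins].astype(int)}))
        smins = np.flatnonzero(rec | (steps > 0))
        step_frames.append(pd.DataFrame(
            {"patient_id": pid, "timestamp": _timestamps(surgery[pid], pod,
                                                         smins),
             "steps": steps[smins]}))
    empty_hr = pd.DataFrame(columns=["patient_id", "timestamp", "hr_bpm"])
    empty_st = pd.DataFrame(columns=["patient_id", "timestamp", "steps"])
    _write("minute_hr",
           pd.concat(hr_frames, ignore_index=True) if hr_frames else empty_hr)
    _write("minute_steps",
           pd.concat(step_frames, ignore_index=True) if step_frames
           else empty_st)
    return paths


def read_cohort(data_dir) -> Cohort:
    """Load a cohort from the CSV dialect written by :func:`write_cohort`
    (or user-supplied files with identical headers)."""
    import os

    def _read(name: str) -> pd.DataFrame:
        return pd.read_csv(os.path.join(data_dir, f"{name}.csv"))

    patients = _read("patients")
    patients["surgery_date"] = pd.to_datetime(patients["surgery_date"])
    events = _read("events")
    if "nsqip" in events.columns and len(events):
        events["nsqip"] = events["nsqip"].astype(bool)
    daily = _read("daily_summary")
    monitoring = (int(patients["monitoring_days"].max())
                  if len(patients) else 21)

    surgery = patients.set_index("patient_id")["surgery_date"]
    hr_csv = _read("minute_hr")
    steps_csv = _read("minute_steps")

    def _pod_minute(df: pd.DataFrame):
        ts = pd.to_datetime(df["timestamp"])
        base = df["patient_id"].map(surgery)
        delta = ts.dt.normalize() - base.dt.normalize()
        return delta.dt.days.to_numpy(), (ts.dt.hour * 60
                                          + ts.dt.minute).to_numpy()

    keys: dict[tuple, int] = {}
    for df in (hr_csv, steps_csv):
        if len(df):
            pods, _ = _pod_minute(df)
            for pid, pod in zip(df["patient_id"], pods):
                keys.setdefault((pid, int(pod)), len(keys))
    n = len(keys)
    pid_arr = np.array([k[0] for k in keys], dtype=object)
    pod_arr = np.array([k[1] for k in keys], dtype=int)
    hr = np.full((n, MINUTES_PER_DAY), np.nan, dtype=np.float32)
    steps = np.zeros((n, MINUTES_PER_DAY), dtype=np.int32)
    if len(hr_csv):
        pods, mins = _pod_minute(hr_csv)
        rows = np.array([keys[(p, int(d))]
                         for p, d in zip(hr_csv["patient_id"], pods)])
        hr[rows, mins] = hr_csv["hr_bpm"].to_numpy(dtype=np.float32)
    if len(steps_csv):
        pods, mins = _pod_minute(steps_csv)
        rows = np.array([keys[(p, int(d))]
                         for p, d in zip(steps_csv["patient_id"], pods)])
        steps[rows, mins] = steps_csv["steps"].to_numpy(dtype=np.int32)

    unknown = set(pid_arr) - set(patients["patient_id"])
    if unknown:
        raise ValueError(
            f"minute streams reference patients absent from the roster: "
            f"{sorted(unknown)}")

    return Cohort(patients=patients, events=events,
                  minutes=MinutePanel(pid_arr, pod_arr, hr, steps),
                  daily_summaries=daily, monitoring_days=monitoring)
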