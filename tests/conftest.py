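"""Shared fixtures: a small fast cohort for unit tests and one full-scale
strong-signal run shared by the signal-recovery, ablation and importance
checks (session-scoped — the LOSO run is the expensive part)."""

import pandas as pd
import pytest

import postopfit as pf

SMALL_SEED = 42
STRONG_SEED = 1234


def small_config(seed=SMALL_SEED, **overrides):
    cfg = pf.CohortConfig(
        complicated=pf.GroupParams(
            n_patients=6, event_rate_per_patient=0.8,
            grade_probs={"I": 0.6, "II": 0.3, "III": 0.1},
            los_mean_days=4.0, los_sd_days=2.0),
        simple=pf.GroupParams(
            n_patients=4, event_rate_per_patient=0.4,
            grade_probs={"I": 0.9, "III": 0.1},
            los_mean_days=0.9, los_sd_days=0.5),
        seed=seed)
    return cfg.with_(**overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_cohort():
    return pf.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    features, wear = pf.build_feature_matrix(small_cohort)
    labels = pf.label_days(small_cohort.events, small_cohort.patients,
                           small_cohort.monitoring_days)
    return {"cohort": small_cohort, "features": features, "wear": wear,
            "labels": labels}


@pytest.fixture(scope="session")
def strong_run():
    """Full-scale cohort at the study conditions (85 complicated + 76 simple
    patients, event rates 41/85 and 10/76, 50% pre-event step suppression,
    +15 bpm HR elevation), LOSO-modeled for the complicated group."""
    cohort = pf.generate_cohort(pf.CohortConfig(seed=STRONG_SEED))
    features, wear = pf.build_feature_matrix(cohort)
    labels = pf.label_days(cohort.events, cohort.patients,
                           cohort.monitoring_days)
    dataset, counts = pf.dataset_assembly(features, wear, labels,
                                          cohort.patients)
    sub = dataset[dataset["group"] == "complicated"]
    params = pf.ModelParams(seed=STRONG_SEED)
    predictions, importances = pf.loso_cv(sub, pf.FEATURE_COLUMNS, params)
    events = cohort.events[
        cohort.events["patient_id"].isin(set(sub["patient_id"]))]
    report = pf.evaluate(predictions, sub, events, importances,
                         group="complicated", ci_reps=200,
                         ci_seed=STRONG_SEED)
    return {"cohort": cohort, "features": features, "wear": wear,
            "labels": labels, "dataset": dataset, "counts": counts,
            "params": params, "predictions": predictions,
            "importances": importances, "report": report}


def make_frames(event_specs, n_patients=2, monitoring_days=21,
                wear_hours=12.0):
    """Hand-built minimal feature/wear/label/patient frames for assembly
    tests. ``event_specs`` is a list of (patient_id, pod) tuples."""
    pids = [f"P{i}" for i in range(n_patients)]
    rows = [(pid, pod) for pid in pids
            for pod in range(1, monitoring_days + 1)]
    features = pd.DataFrame(rows, columns=["patient_id", "pod"])
    features["total_steps"] = 1000.0
    wear = features[["patient_id", "pod"]].copy()
    wear["wear_hours_waking"] = wear_hours
    wear["any_data"] = True
    patients = pd.DataFrame({
        "patient_id": pids, "group": "complicated", "device": "inspire_hr"})
    events = pd.DataFrame(
        [(pid, pod, "symptom", "I", False) for pid, pod in event_specs],
        columns=["patient_id", "pod", "category", "clavien_grade", "nsqip"])
    labels = pf.label_days(events, patients, monitoring_days)
    return features, wear, labels, patients, events
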