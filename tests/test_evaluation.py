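"""Day-level metrics, event-level detection, bootstrap CIs, importance
averaging and sensitivity variants."""

import itertools

import numpy as np
import pandas as pd
import pytest

import postopfit as pf
from postopfit.evaluation import EvalReport

from conftest import make_frames


# ---------------------------------------------------------------------------
# confusion / rates
# ---------------------------------------------------------------------------

def test_confusion_all_correct():
    out = pf.confusion_and_rates([0, 0, 1, 1], [0, 0, 1, 1])
    assert out["pct_normal_correct"] == out["pct_abnormal_correct"] == 100.0


def test_confusion_worked_example():
    actual = [0, 0, 0, 0, 1, 1, 1, 1]
    predicted = [0, 0, 0, 1, 1, 1, 1, 0]
    out = pf.confusion_and_rates(predicted, actual)
    assert (out["tn"], out["fp"], out["fn"], out["tp"]) == (3, 1, 1, 3)
    assert out["pct_normal_correct"] == 75.0
    assert out["pct_abnormal_correct"] == 75.0


def test_confusion_empty_class_undefined():
    out = pf.confusion_and_rates([0, 1], [0, 0])
    assert out["pct_abnormal_correct"] is None


# ---------------------------------------------------------------------------
# AUROC / AUPRC
# ---------------------------------------------------------------------------

def brute_force_auroc(scores, labels):
    """Exhaustive pairwise concordance (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auroc_trivial_cases():
    assert pf.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert pf.auroc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
    assert pf.auroc([0.5, 0.6], [1, 1]) is None


def test_auroc_matches_pairwise_concordance_on_toy_set():
    scores = [0.1, 0.9, 0.4, 0.4, 0.7, 0.2]
    labels = [0, 1, 0, 1, 1, 0]
    assert pf.auroc(scores, labels) == pytest.approx(
        brute_force_auroc(scores, labels))


def test_auprc_trivial_and_baseline():
    assert pf.auprc([0.2, 0.7], [1, 1]) == 1.0
    assert pf.auprc([0.2, 0.7], [0, 0]) is None
    y = np.array([1] * 74 + [0] * (1581 - 74))
    assert pf.prevalence_baseline(y) == 74 / 1581


def test_random_scorer_auprc_approaches_prevalence():
    """The expected AUPRC of a random scorer equals the positive
    prevalence."""
    rng = np.random.default_rng(0)
    y = np.array([1] * 15 + [0] * 135)
    p = y.mean()
    vals = [pf.auprc(rng.random(len(y)), y) for _ in range(200)]
    assert np.mean(vals) == pytest.approx(p, abs=0.03)


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def _toy_predictions(n_patients=8, days=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        for d in range(days):
            y = int(rng.random() < 0.3)
            rows.append({"patient_id": f"P{p}", "pod": d + 1,
                         "score": 0.6 * y + 0.4 * rng.random(), "_y": y})
    df = pd.DataFrame(rows)
    return df, df["_y"].to_numpy()


def test_bootstrap_ci_constant_metric_zero_width():
    preds, y = _toy_predictions()
    lo, hi = pf.bootstrap_ci(lambda s, yy: 0.7, preds, y, reps=50, seed=0)
    assert lo == hi == 0.7


def test_bootstrap_ci_brackets_point_estimate():
    preds, y = _toy_predictions()
    point = pf.auroc(preds["score"].to_numpy(), y)
    lo, hi = pf.bootstrap_ci(pf.auroc, preds, y, reps=500, seed=1)
    assert 0.0 <= lo <= point <= hi <= 1.0


def test_bootstrap_ci_monte_carlo_stability():
    preds, y = _toy_predictions(n_patients=12, days=15)
    a = pf.bootstrap_ci(pf.auroc, preds, y, reps=2000, seed=7)
    b = pf.bootstrap_ci(pf.auroc, preds, y, reps=4000, seed=7)
    assert abs(a[0] - b[0]) < 0.02 and abs(a[1] - b[1]) < 0.02


def test_bootstrap_ci_missing_when_mostly_degenerate():
    # single patient whose days are all normal: every resample is degenerate
    preds = pd.DataFrame({"patient_id": ["A"] * 5, "pod": range(1, 6),
                          "score": np.linspace(0, 1, 5)})
    assert pf.bootstrap_ci(pf.auroc, preds, np.zeros(5, dtype=int),
                           reps=40, seed=0) is None


# ---------------------------------------------------------------------------
# event-level detection
# ---------------------------------------------------------------------------

def _preds(rows):
    return pd.DataFrame(rows, columns=["patient_id", "pod", "predicted"]) \
        .assign(score=lambda d: (d["predicted"] == "abnormal").astype(float))


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "pod", "category",
                                       "clavien_grade", "nsqip"])


def test_event_detected_at_d2_only():
    preds = _preds([("A", 3, "abnormal"), ("A", 4, "normal")])
    out = pf.event_detection(preds, _events([("A", 5, "symptom", "I",
                                              False)]))
    assert out["d_minus2_counts"] == (1, 1)
    assert out["d_minus1_counts"] == (0, 1)
    assert out["d_any_counts"] == (1, 1)
    assert out["n_events_missed"] == 0


def test_pod1_event_excluded_from_all_denominators():
    preds = _preds([("A", 1, "abnormal"), ("A", 2, "abnormal")])
    out = pf.event_detection(preds, _events([("A", 1, "symptom", "I",
                                              False)]))
    assert out["d_minus2_counts"] == (0, 0)
    assert out["d_minus1_counts"] == (0, 0)
    assert out["d_any_counts"] == (0, 0)
    assert out["d_any_pct"] is None


def test_pod2_event_only_in_d1_denominator():
    preds = _preds([("A", 1, "abnormal")])
    out = pf.event_detection(preds, _events([("A", 2, "symptom", "I",
                                              False)]))
    assert out["d_minus2_counts"] == (0, 0)
    assert out["d_minus1_counts"] == (1, 1)
    assert out["d_any_counts"] == (1, 1)


def test_no_abnormal_predictions_all_missed():
    preds = _preds([("A", 3, "normal"), ("A", 4, "normal")])
    out = pf.event_detection(preds, _events([("A", 5, "complication", "III",
                                              True)]))
    assert out["d_any_pct"] == 0.0
    assert out["n_events_missed"] == 1
    assert out["missed_events"][0]["clavien_grade"] == "III"


def test_event_for_unknown_patient_rejected():
    preds = _preds([("A", 3, "normal")])
    with pytest.raises(ValueError, match="GHOST"):
        pf.event_detection(preds, _events([("GHOST", 5, "symptom", "I",
                                            False)]))


# ---------------------------------------------------------------------------
# importance averaging
# ---------------------------------------------------------------------------

def test_average_importance_two_folds():
    imps = pd.DataFrame([{"a": 0.6, "b": 0.4}, {"a": 0.2, "b": 0.8}])
    out = dict(pf.average_importance(imps))
    assert out["a"] == pytest.approx(0.4)
    assert out["b"] == pytest.approx(0.6)


def test_average_importance_missing_feature_counts_zero():
    imps = pd.DataFrame([{"a": 1.0, "b": np.nan}, {"a": 0.5, "b": 0.5}])
    out = dict(pf.average_importance(imps))
    assert out["b"] == pytest.approx(0.25 / 1.0)


# ---------------------------------------------------------------------------
# report serialization and sensitivity plumbing
# ---------------------------------------------------------------------------

def test_report_json_round_trip(tmp_path):
    rep = EvalReport(
        group="complicated", n_days=100, n_abnormal=5, tn=80, fp=15, fn=1,
        tp=4, pct_normal_correct=84.2, pct_abnormal_correct=80.0,
        auroc=0.8, auroc_ci=(0.76, 0.83), auprc=0.36, auprc_ci=(0.11, 0.82),
        baseline_auprc=0.05, d_minus2_pct=76.0, d_minus1_pct=73.0,
        d_any_pct=83.0, d_minus2_counts=(31, 41), d_minus1_counts=(29, 40),
        d_any_counts=(34, 41), n_events_missed=7,
        missed_events=[{"patient_id": "A", "pod": 5, "clavien_grade": "I",
                        "category": "symptom"}],
        importance=[("total_steps", 0.2)])
    path = tmp_path / "report.json"
    rep.to_json(path)
    import json
    loaded = EvalReport.from_dict(json.loads(path.read_text()))
    assert loaded == rep


def test_unknown_sensitivity_variant_rejected():
    features, wear, labels, patients, events = make_frames([("P0", 5)])
    with pytest.raises(ValueError, match="unknown sensitivity variant"):
        pf.run_sensitivity("bogus", features, wear, labels, events, patients,
                           pf.ModelParams(seed=0))


def test_sensitivity_aborts_when_too_few_patients():
    features, wear, labels, patients, events = make_frames([("P0", 5)])
    patients["device"] = "inspire_hr"
    with pytest.raises(ValueError, match="too few"):
        pf.run_sensitivity("device_only", features, wear, labels, events,
                           patients, pf.ModelParams(seed=0),
                           device="inspire_2")


def test_combined_groups_day_conservation(small_tables):
    """Combined-model day totals equal the sum of the per-group included
    days."""
    t = small_tables
    dataset, manifest = pf.dataset_assembly(t["features"], t["wear"],
                                            t["labels"],
                                            t["cohort"].patients)
    assert manifest["total"]["n_days"] == \
        manifest["complicated"]["n_days"] + manifest["simple"]["n_days"]
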