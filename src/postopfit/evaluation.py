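"""Performance evaluation and sensitivity analyses.

Computes the day-level and event-level performance surfaces of the detection
pipeline: pooled confusion matrix and percent-correct rates, AUROC and AUPRC
with patient-level bootstrap confidence intervals, the prevalence baseline a
random scorer would achieve on the precision-recall curve, early-detection
rates at the event level (d-2: abnormal prediction exactly two days before an
event; d-1: exactly one day before; d_ANY: on either day), and feature
importance averaged over cross-validation folds.

Four sensitivity analyses re-run the full LOSO pipeline under modified
conditions: (1) clinical/demographic features only (no wearable data),
(2) a >= 10 h wear-time compliance filter over 06:00-24:00, (3) a single
device generation, and (4) both severity groups pooled into one model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import CLINICAL_DEMOGRAPHIC_FEATURES, FEATURE_COLUMNS
from .labeling import LABEL_ABNORMAL, dataset_assembly
from .model import ModelParams, loso_cv

logger = logging.getLogger(__name__)

SENSITIVITY_VARIANTS = ("no_fitbit", "min_wear_10h", "device_only",
                        "combined_groups")


@dataclass
class EvalReport:
    """Pooled evaluation of one model run (one group or variant)."""

    group: str
    n_days: int
    n_abnormal: int
    tn: int
    fp: int
    fn: int
    tp: int
    pct_normal_correct: float | None
    pct_abnormal_correct: float | None
    auroc: float | None
    auroc_ci: tuple[float, float] | None
    auprc: float | None
    auprc_ci: tuple[float, float] | None
    baseline_auprc: float
    d_minus2_pct: float | None
    d_minus1_pct: float | None
    d_any_pct: float | None
    d_minus2_counts: tuple[int, int] = (0, 0)   # (detected, denominator)
    d_minus1_counts: tuple[int, int] = (0, 0)
    d_any_counts: tuple[int, int] = (0, 0)
    n_events_missed: int = 0
    missed_events: list = field(default_factory=list)
    importance: list = field(default_factory=list)   # [(feature, weight)]
    variant: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        for k in ("auroc_ci", "auprc_ci", "d_minus2_counts",
                  "d_minus1_counts", "d_any_counts"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        d["importance"] = [tuple(x) for x in d.get("importance", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# day-level metrics
# ---------------------------------------------------------------------------

def confusion_and_rates(predicted: np.ndarray, actual: np.ndarray) -> dict:
    """2x2 confusion counts and percent-correct rates over included days.

    ``predicted`` and ``actual`` are binary (1 = abnormal). An empty class
    makes its percent-correct undefined (None), never zero.
    """
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    tp = int(((predicted == 1) & (actual == 1)).sum())
    tn = int(((predicted == 0) & (actual == 0)).sum())
    fp = int(((predicted == 1) & (actual == 0)).sum())
    fn = int(((predicted == 0) & (actual == 1)).sum())
    pct_abn = 100.0 * tp / (tp + fn) if (tp + fn) else None
    pct_nrm = 100.0 * tn / (tn + fp) if (tn + fp) else None
    return {"tn": tn, "fp": fp, "fn": fn, "tp": tp,
            "pct_normal_correct": pct_nrm, "pct_abnormal_correct": pct_abn}


def auroc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Area under the ROC curve: the probability that a random abnormal day
    outscores a random normal day, ties counted 1/2 (Mann-Whitney). Undefined
    (None) when only one class is present."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Area under the precision-recall curve by the interpolation-free step
    method (average precision). Undefined without positives."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        return None
    return float(average_precision_score(labels,
                                         np.asarray(scores, dtype=float)))


def prevalence_baseline(labels: np.ndarray) -> float:
    """AUPRC of a random scorer: the positive-class prevalence, exactly."""
    labels = np.asarray(labels, dtype=int)
    return float(labels.sum()) / len(labels) if len(labels) else float("nan")


def bootstrap_ci(metric, predictions: pd.DataFrame, labels: np.ndarray,
                 level: float = 0.90, reps: int = 1000, seed: int = 0
                 ) -> tuple[float, float] | None:
    """Patient-level percentile bootstrap interval for a pooled metric.

    Patients are resampled with replacement and their days pooled; resamples
    with a single class are skipped. If more than half the resamples are
    degenerate the interval is reported missing (None) with a diagnostic.
    """
    df = predictions.copy()
    df["_label"] = np.asarray(labels, dtype=int)
    by_patient = {pid: (grp["score"].to_numpy(), grp["_label"].to_numpy())
                  for pid, grp in df.groupby("patient_id")}
    pids = list(by_patient)
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(reps):
        take = rng.choice(len(pids), size=len(pids), replace=True)
        s = np.concatenate([by_patient[pids[i]][0] for i in take])
        y = np.concatenate([by_patient[pids[i]][1] for i in take])
        v = metric(s, y)
        if v is not None and not np.isnan(v):
            values.append(v)
    if len(values) < reps / 2:
        logger.warning("bootstrap CI missing: %d/%d resamples degenerate",
                       reps - len(values), reps)
        return None
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# event-level early detection
# ---------------------------------------------------------------------------

def event_detection(predictions: pd.DataFrame, events: pd.DataFrame) -> dict:
    """Early-detection rates per event.

    An event on POD k is detected at d-2 (d-1) iff the model predicted
    abnormal on POD k-2 (k-1) and that day exists in the modeling table. The
    d-2 denominator excludes events on POD <= 2, the d-1 denominator events
    on POD 1; d_ANY counts events with at least one existing labeled prior
    day. Events with no existing prior day are excluded from all three.
    Missed events (in the d_ANY denominator but undetected on both days) are
    listed with their Clavien grade.
    """
    pred_map = {(r.patient_id, int(r.pod)): r.predicted == "abnormal"
                for r in predictions.itertuples()}
    known_patients = set(predictions["patient_id"])
    d2_num = d2_den = d1_num = d1_den = dany_num = dany_den = 0
    missed = []
    for ev in events.itertuples():
        if ev.patient_id not in known_patients:
            raise ValueError(f"event for patient {ev.patient_id!r} absent "
                             "from predictions")
        pod = int(ev.pod)
        k2 = (ev.patient_id, pod - 2)
        k1 = (ev.patient_id, pod - 1)
        det2 = pred_map.get(k2, False) if pod > 2 else False
        det1 = pred_map.get(k1, False) if pod > 1 else False
        if pod > 2:
            d2_den += 1
            d2_num += det2
        if pod > 1:
            d1_den += 1
            d1_num += det1
        has_prior = (pod > 2 and k2 in pred_map) or (pod > 1
                                                     and k1 in pred_map)
        if has_prior:
            dany_den += 1
            if det2 or det1:
                dany_num += 1
            else:
                missed.append({"patient_id": ev.patient_id, "pod": pod,
                               "clavien_grade": ev.clavien_grade,
                               "category": ev.category})
    pct = lambda num, den: 100.0 * num / den if den else None
    return {
        "d_minus2_pct": pct(d2_num, d2_den),
        "d_minus1_pct": pct(d1_num, d1_den),
        "d_any_pct": pct(dany_num, dany_den),
        "d_minus2_counts": (d2_num, d2_den),
        "d_minus1_counts": (d1_num, d1_den),
        "d_any_counts": (dany_num, dany_den),
        "n_events_missed": len(missed),
        "missed_events": missed,
    }


def average_importance(importances: pd.DataFrame) -> list[tuple[str, float]]:
    """Mean Gini importance per feature across folds, normalized to sum to 1
    and ranked descending. A feature a fold did not retain contributes 0 for
    that fold."""
    mean = importances.fillna(0.0).mean(axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    return list(mean.sort_values(ascending=False).items())


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def evaluate(predictions: pd.DataFrame, dataset: pd.DataFrame,
             events: pd.DataFrame, importances: pd.DataFrame,
             group: str = "all", variant: str | None = None,
             ci_reps: int = 1000, ci_seed: int = 0) -> EvalReport:
    """Assemble the full evaluation report from LOSO predictions."""
    merged = dataset[["patient_id", "pod", "label"]].merge(
        predictions, on=["patient_id", "pod"], how="inner")
    if (merged["label"] == "excluded").any():
        raise ValueError("excluded days present in evaluation input")
    y = (merged["label"] == LABEL_ABNORMAL).astype(int).to_numpy()
    yhat = (merged["predicted"] == "abnormal").astype(int).to_numpy()
    scores = merged["score"].to_numpy()

    conf = confusion_and_rates(yhat, y)
    det = event_detection(
        merged.rename(columns={"predicted": "predicted"}),
        events[events["patient_id"].isin(set(merged["patient_id"]))])
    return EvalReport(
        group=group, variant=variant,
        n_days=int(len(merged)), n_abnormal=int(y.sum()), **conf,
        auroc=auroc(scores, y),
        auroc_ci=bootstrap_ci(auroc, merged, y, reps=ci_reps, seed=ci_seed),
        auprc=auprc(scores, y),
        auprc_ci=bootstrap_ci(auprc, merged, y, reps=ci_reps, seed=ci_seed),
        baseline_auprc=prevalence_baseline(y),
        importance=average_importance(importances),
        **det,
    )


def run_group_pipeline(dataset: pd.DataFrame, events: pd.DataFrame,
                       params: ModelParams, group: str,
                       feature_columns: list[str] | None = None,
                       variant: str | None = None,
                       ci_reps: int = 1000) -> tuple[EvalReport,
                                                     pd.DataFrame]:
    """LOSO-train and evaluate one modeling table; returns (report,
    predictions)."""
    cols = feature_columns or FEATURE_COLUMNS
    cols = [c for c in cols if c in dataset.columns]
    predictions, importances = loso_cv(dataset, cols, params)
    report = evaluate(predictions, dataset, events, importances, group=group,
                      variant=variant, ci_reps=ci_reps, ci_seed=params.seed)
    return report, predictions


def run_sensitivity(variant: str, features: pd.DataFrame, wear: pd.DataFrame,
                    labels: pd.DataFrame, events: pd.DataFrame,
                    patients: pd.DataFrame, params: ModelParams,
                    group: str = "complicated", device: str = "inspire_hr",
                    ci_reps: int = 1000) -> EvalReport:
    """Run one of the four sensitivity analyses end to end.

    ``no_fitbit`` restricts features to clinical + demographic columns;
    ``min_wear_10h`` drops days under 10 worn hours in 06:00-24:00;
    ``device_only`` keeps patients on one device generation;
    ``combined_groups`` pools both severity groups into a single model.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}; expected "
                         f"one of {SENSITIVITY_VARIANTS}")
    min_wear = 10.0 if variant == "min_wear_10h" else None
    dataset, _ = dataset_assembly(features, wear, labels, patients,
                                  min_wear_hours=min_wear)
    feature_columns = (CLINICAL_DEMOGRAPHIC_FEATURES
                       if variant == "no_fitbit" else None)
    if variant == "device_only":
        dataset = dataset[dataset["device"] == device]
    if variant != "combined_groups":
        dataset = dataset[dataset["group"] == group]
        label_tag = group
    else:
        label_tag = "combined"

    if dataset["patient_id"].nunique() < 2 or \
            (dataset["label"] == LABEL_ABNORMAL).sum() < 2:
        raise ValueError(f"sensitivity variant {variant!r} leaves too few "
                         "patients or abnormal days to model")
    ev = events[events["patient_id"].isin(set(dataset["patient_id"]))]
    report, _ = run_group_pipeline(dataset, ev, params, group=label_tag,
                                   feature_columns=feature_columns,
                                   variant=variant, ci_reps=ci_reps)
    return report


# ---------------------------------------------------------------------------
# plots (optional, for the CLI report command)
# ---------------------------------------------------------------------------

def plot_report(report: EvalReport, predictions: pd.DataFrame,
                dataset: pd.DataFrame, out_dir) -> list:
    """Write ROC, PR, confusion-matrix and top-15-importance figures."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import precision_recall_curve, roc_curve

    merged = dataset[["patient_id", "pod", "label"]].merge(
        predictions, on=["patient_id", "pod"])
    y = (merged["label"] == LABEL_ABNORMAL).astype(int)
    paths = []
    os.makedirs(out_dir, exist_ok=True)

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    fpr, tpr, _ = roc_curve(y, merged["score"])
    axes[0, 0].plot(fpr, tpr)
    axes[0, 0].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[0, 0].set(title=f"ROC (AUROC={report.auroc:.2f})",
                   xlabel="1 - specificity", ylabel="sensitivity")
    prec, rec, _ = precision_recall_curve(y, merged["score"])
    axes[0, 1].plot(rec, prec)
    axes[0, 1].axhline(report.baseline_auprc, ls="--", c="k", lw=0.8)
    axes[0, 1].set(title=f"PR (AUPRC={report.auprc:.2f})", xlabel="recall",
                   ylabel="precision")
    cm = np.array([[report.tn, report.fp], [report.fn, report.tp]])
    axes[1, 0].imshow(cm, cmap="Blues")
    for (r, c), v in np.ndenumerate(cm):
        axes[1, 0].text(c, r, str(v), ha="center", va="center")
    axes[1, 0].set(title="Confusion matrix", xticks=[0, 1], yticks=[0, 1],
                   xticklabels=["pred normal", "pred abnormal"],
                   yticklabels=["normal", "abnormal"])
    top = report.importance[:15][::-1]
    axes[1, 1].barh([t[0] for t in top], [t[1] for t in top])
    axes[1, 1].set(title="Top 15 features (mean Gini importance)")
    fig.tight_layout()
    path = os.path.join(out_dir, f"report_{report.group}.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths
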