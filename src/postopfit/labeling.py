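"""Ground-truth day labeling around postoperative events.

Each monitored postoperative day (POD) is labeled **normal**, **abnormal**, or
**excluded**:

* the 1-2 days leading up to a newly reported postoperative event are
  abnormal — for an event on POD k, PODs k-2 and k-1 (those that exist and
  are >= 1) are abnormal; an event on POD 2 yields a single abnormal day
  (POD 1); an event on POD 1 yields none;
* the event day itself is excluded from model training and testing, and
  exclusion takes precedence when a day is simultaneously inside another
  event's pre-event window;
* every remaining day is normal. Days after an event revert to normal unless
  captured by a later event's window.

Both abnormal symptoms and confirmed complications are "postoperative events"
and generate windows identically; the NSQIP designation only decides which
category an event is reported under.
"""

from __future__ import annotations

import warnings

import pandas as pd

LABEL_NORMAL = "normal"
LABEL_ABNORMAL = "abnormal"
LABEL_EXCLUDED = "excluded"

#: collision precedence when rules overlap on a day
_PRECEDENCE = {LABEL_NORMAL: 0, LABEL_ABNORMAL: 1, LABEL_EXCLUDED: 2}


def classify_event(clavien_grade: str, nsqip: bool) -> str:
    """Event category: a confirmed NSQIP complication, else an abnormal
    symptom. Grade IV/V events are accepted but flagged as exceedingly rare
    after appendectomy."""
    if clavien_grade not in {"I", "II", "III", "IV", "V"}:
        raise ValueError(f"unknown Clavien-Dindo grade {clavien_grade!r}")
    if clavien_grade in {"IV", "V"}:
        warnings.warn(f"Clavien-Dindo grade {clavien_grade} event: "
                      "exceedingly rare after appendectomy (<1%)")
    return "complication" if nsqip else "symptom"


def label_patient_days(event_pods: list[int], monitoring_days: int = 21
                       ) -> dict[int, str]:
    """Labels for PODs 1..monitoring_days of one patient given event PODs."""
    labels = {pod: LABEL_NORMAL for pod in range(1, monitoring_days + 1)}

    def _apply(pod: int, label: str) -> None:
        if 1 <= pod <= monitoring_days and \
                _PRECEDENCE[label] > _PRECEDENCE[labels[pod]]:
            labels[pod] = label

    for k in event_pods:
        if not 1 <= k <= monitoring_days:
            raise ValueError(f"event POD {k} outside monitoring window "
                             f"1..{monitoring_days}")
        _apply(k - 2, LABEL_ABNORMAL)
        _apply(k - 1, LABEL_ABNORMAL)
        _apply(k, LABEL_EXCLUDED)
    return labels


def label_days(events: pd.DataFrame, patients: pd.DataFrame,
               monitoring_days: int = 21) -> pd.DataFrame:
    """Day labels for every patient in the roster.

    Duplicate event records (same patient, POD, category) are collapsed with
    a warning before labeling. Returns (patient_id, pod, label) with exactly
    ``monitoring_days`` rows per patient.
    """
    if len(events):
        deduped = events.drop_duplicates(
            subset=["patient_id", "pod", "category"])
        if len(deduped) < len(events):
            warnings.warn(f"collapsed {len(events) - len(deduped)} duplicate "
                          "event record(s) (same patient, POD, category)")
        events = deduped

    rows = []
    for pid in patients["patient_id"]:
        pods = (events.loc[events["patient_id"] == pid, "pod"].astype(int)
                .tolist() if len(events) else [])
        for pod, label in label_patient_days(pods, monitoring_days).items():
            rows.append((pid, pod, label))
    return pd.DataFrame(rows, columns=["patient_id", "pod", "label"])


def dataset_assembly(features: pd.DataFrame, wear: pd.DataFrame,
                     labels: pd.DataFrame, patients: pd.DataFrame,
                     min_wear_hours: float | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Join features, wear and labels into the modeling table.

    Rows are patient-days with any recorded data and a label other than
    excluded. With ``min_wear_hours`` set (the wear-time sensitivity
    analysis), days below the threshold are additionally dropped; days of
    sufficient wear before and after a dropped day keep their original
    labels. Returns the table plus a manifest of per-group day/abnormal
    counts.
    """
    if features.empty:
        empty = features.copy()
        for c in ("label", "wear_hours_waking", "group", "device"):
            empty[c] = pd.Series(dtype=object)
        return empty, {"total": {"n_days": 0, "n_abnormal": 0,
                                 "n_patients": 0}}
    merged = features.merge(
        labels, on=["patient_id", "pod"], how="left", validate="one_to_one")
    if merged["label"].isna().any():
        bad = merged.loc[merged["label"].isna(), ["patient_id", "pod"]]
        raise ValueError("label missing for included day(s): "
                         f"{bad.to_records(index=False).tolist()[:5]}")
    merged = merged.merge(
        wear[["patient_id", "pod", "wear_hours_waking"]],
        on=["patient_id", "pod"], how="left")
    merged = merged[merged["label"] != LABEL_EXCLUDED]
    if min_wear_hours is not None:
        merged = merged[merged["wear_hours_waking"] >= min_wear_hours]
    merged = merged.merge(patients[["patient_id", "group", "device"]],
                          on="patient_id", how="left")
    merged = merged.reset_index(drop=True)

    manifest = {}
    for group, sub in merged.groupby("group"):
        manifest[group] = {
            "n_days": int(len(sub)),
            "n_abnormal": int((sub["label"] == LABEL_ABNORMAL).sum()),
            "n_patients": int(sub["patient_id"].nunique()),
        }
    manifest["total"] = {
        "n_days": int(len(merged)),
        "n_abnormal": int((merged["label"] == LABEL_ABNORMAL).sum()),
        "n_patients": int(merged["patient_id"].nunique()),
    }
    return merged, manifest
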