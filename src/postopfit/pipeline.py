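"""End-to-end orchestration: simulate -> features -> label -> train-eval ->
report, with a run manifest tying every output to the config and seed.

Separate models are trained for the complicated and simple appendicitis
groups (the default protocol); the combined-group model is a sensitivity
analysis, not the default. All protocol thresholds (0.95 correlation, 10 h
wear, 06:00-24:00 waking window, 2-day label window, 21 monitoring days) are
named config keys with protocol defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import run_group_pipeline
from .features import build_feature_matrix
from .labeling import LABEL_ABNORMAL, dataset_assembly, label_days
from .model import ModelParams
from .synthetic_cohort import (CohortConfig, GroupParams, PreEventEffect,
                               SUMMARY_FIELDS, generate_cohort, read_cohort,
                               write_cohort)

logger = logging.getLogger("postopfit")
GROUPS = ("complicated", "simple")


def setup_logging(log_path=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_path:
        handlers.append(logging.FileHandler(log_path))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s "
                               "%(message)s")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Full pipeline configuration with protocol defaults, as a plain dict
    (serializable to YAML)."""
    return {
        "cohort": dataclasses.asdict(CohortConfig()),
        "model": dataclasses.asdict(ModelParams()),
        "evaluation": {"ci_reps": 1000, "min_wear_hours": None},
        "labeling": {"pre_event_window_days": 2},
    }


def load_config(path=None) -> dict:
    config = default_config()
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in config:
                raise ValueError(f"unknown config section {section!r}")
            if isinstance(values, dict):
                _merge(config[section], values, section)
            else:
                config[section] = values
    return config


#: dict-valued config leaves replaced wholesale rather than key-merged
_REPLACE_WHOLESALE = {"grade_probs", "race_probs", "nsqip_prob_by_grade"}


def _merge(base: dict, update: dict, path: str) -> None:
    for k, v in update.items():
        if k not in base:
            raise ValueError(f"unknown config key {path}.{k}")
        if isinstance(base[k], dict) and isinstance(v, dict) \
                and k not in _REPLACE_WHOLESALE:
            _merge(base[k], v, f"{path}.{k}")
        else:
            base[k] = v


def cohort_config_from_dict(d: dict, seed: int | None = None) -> CohortConfig:
    d = dict(d)
    for g in GROUPS:
        d[g] = GroupParams(**d[g])
    d["pre_event_effect"] = PreEventEffect(**d["pre_event_effect"])
    if seed is not None:
        d["seed"] = seed
    return CohortConfig(**d)


def model_params_from_dict(d: dict, seed: int | None = None) -> ModelParams:
    d = dict(d)
    if seed is not None:
        d["seed"] = seed
    return ModelParams(**d)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int | None) -> str:
    digests = {}
    for root, _, files in os.walk(out_dir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            path = os.path.join(root, f)
            digests[os.path.relpath(path, out_dir)] = _sha256(path)
    manifest = {
        "package": "postopfit",
        "version": __version__,
        "seed": seed,
        "config": config,
        "digests": digests,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def run_all(config: dict, out_dir, seed: int | None = None,
            data_dir=None, write_cohort_csvs: bool = False,
            make_plots: bool = False) -> dict:
    """Execute the full pipeline; returns {group: EvalReport}.

    With ``data_dir`` the cohort is loaded from CSVs instead of simulated.
    Each severity group is modeled separately; a group whose data cannot
    support a model (e.g. fewer than 2 abnormal days) is skipped with a
    diagnostic rather than aborting the run.
    """
    os.makedirs(out_dir, exist_ok=True)
    stage = "simulate"
    try:
        if data_dir:
            cohort = read_cohort(data_dir)
        else:
            cohort = generate_cohort(
                cohort_config_from_dict(config["cohort"], seed))
            if write_cohort_csvs:
                write_cohort(cohort, os.path.join(out_dir, "cohort"))

        stage = "features"
        features, wear = build_feature_matrix(cohort)
        features.to_csv(os.path.join(out_dir, "features.csv"), index=False,
                        lineterminator="\n", float_format="%.6g")
        wear.to_csv(os.path.join(out_dir, "wear.csv"), index=False,
                    lineterminator="\n", float_format="%.6g")

        stage = "label"
        labels = label_days(cohort.events, cohort.patients,
                            cohort.monitoring_days)
        labels.to_csv(os.path.join(out_dir, "labels.csv"), index=False,
                      lineterminator="\n")

        stage = "assemble"
        dataset, counts = dataset_assembly(
            features, wear, labels, cohort.patients,
            min_wear_hours=config["evaluation"].get("min_wear_hours"))
        with open(os.path.join(out_dir, "dataset_manifest.json"), "w") as fh:
            json.dump(counts, fh, indent=2)

        params = model_params_from_dict(config["model"], seed)
        ci_reps = int(config["evaluation"].get("ci_reps", 1000))
        reports = {}
        for group in GROUPS:
            stage = f"train-eval[{group}]"
            sub = dataset[dataset["group"] == group]
            n_abn = int((sub["label"] == LABEL_ABNORMAL).sum())
            if sub["patient_id"].nunique() < 2 or n_abn < 2:
                logger.warning("group %s skipped: %d patients, %d abnormal "
                               "days — not enough to model", group,
                               sub["patient_id"].nunique(), n_abn)
                continue
            ev = cohort.events[
                cohort.events["patient_id"].isin(set(sub["patient_id"]))]
            report, predictions = run_group_pipeline(
                sub, ev, params, group=group, ci_reps=ci_reps)
            reports[group] = report
            predictions.to_csv(
                os.path.join(out_dir, f"predictions_{group}.csv"),
                index=False, lineterminator="\n", float_format="%.6g")
            report.to_json(os.path.join(out_dir, f"report_{group}.json"))
            pd.DataFrame(report.importance,
                         columns=["feature", "mean_gini_importance"]).head(
                15).to_csv(os.path.join(out_dir,
                                        f"importance_top15_{group}.csv"),
                           index=False, lineterminator="\n",
                           float_format="%.6g")
            if make_plots:
                from .evaluation import plot_report
                plot_report(report, predictions, sub, out_dir)
    except Exception:
        logger.error("pipeline aborted at stage %r; partial outputs "
                     "preserved in %s", stage, out_dir)
        raise

    write_manifest(out_dir, config, seed)
    return reports


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

_REQUIRED = {
    "patients": ["patient_id", "group", "age_years", "sex", "race_ethnicity",
                 "weight_kg", "height_cm", "device", "length_of_stay_days",
                 "monitoring_days", "surgery_date"],
    "events": ["patient_id", "pod", "category", "clavien_grade", "nsqip"],
    "daily_summary": ["patient_id", "pod"],
    "minute_hr": ["patient_id", "timestamp", "hr_bpm"],
    "minute_steps": ["patient_id", "timestamp", "steps"],
}


def validate_inputs(data_dir) -> list[dict]:
    """Schema and invariant checks over a CSV data directory.

    Returns a list of diagnostics ({file, row, message}); an empty list means
    the directory is valid. Malformed rows are reported, not thrown."""
    diags: list[dict] = []

    def add(file, row, message):
        diags.append({"file": file, "row": row, "message": message})

    tables = {}
    for name, required in _REQUIRED.items():
        path = os.path.join(data_dir, f"{name}.csv")
        if not os.path.exists(path):
            add(f"{name}.csv", None, "file missing")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV is a diagnostic, not a crash
            add(f"{name}.csv", None, f"unreadable: {exc}")
            continue
        for col in required:
            if col not in df.columns:
                add(f"{name}.csv", None, f"missing required column {col!r}")
        tables[name] = df

    p = tables.get("patients")
    if p is not None and "patient_id" in p:
        dup = p[p["patient_id"].duplicated()]
        for i in dup.index:
            add("patients.csv", int(i), "duplicate patient_id")
        if "age_years" in p:
            for i in p.index[(p["age_years"] < 3) | (p["age_years"] > 17)]:
                add("patients.csv", int(i), "age_years outside [3, 17]")
        if "length_of_stay_days" in p:
            for i in p.index[p["length_of_stay_days"] < 0]:
                add("patients.csv", int(i), "negative length_of_stay_days")
        known = set(p["patient_id"])
        monitoring = p.set_index("patient_id").get("monitoring_days")
    else:
        known, monitoring = set(), None

    e = tables.get("events")
    if e is not None and {"patient_id", "pod"} <= set(e.columns):
        for i, row in e.iterrows():
            if known and row["patient_id"] not in known:
                add("events.csv", int(i),
                    f"unknown patient_id {row['patient_id']!r}")
            elif monitoring is not None and \
                    row["pod"] > monitoring.get(row["patient_id"], 21):
                add("events.csv", int(i),
                    f"event POD {row['pod']} exceeds monitoring window")
            if row["pod"] < 1:
                add("events.csv", int(i), f"event POD {row['pod']} < 1")
        if "nsqip" in e and "category" in e:
            bad = e[(e["nsqip"].astype(bool)) & (e["category"] !=
                                                 "complication")]
            for i in bad.index:
                add("events.csv", int(i),
                    "nsqip=true requires category=complication")

    d = tables.get("daily_summary")
    if d is not None:
        numeric = [c for c in SUMMARY_FIELDS if c in d.columns]
        for c in numeric:
            vals = pd.to_numeric(d[c], errors="coerce")
            for i in d.index[vals < 0]:
                add("daily_summary.csv", int(i), f"negative {c}")
        if {"total_min_asleep", "total_min_in_bed"} <= set(d.columns):
            both = d["total_min_asleep"].notna() & d["total_min_in_bed"].notna()
            bad = d.index[both & (d["total_min_asleep"] >
                                  d["total_min_in_bed"])]
            for i in bad:
                add("daily_summary.csv", int(i),
                    "total_min_asleep exceeds total_min_in_bed")

    for name, col in (("minute_hr", "hr_bpm"), ("minute_steps", "steps")):
        t = tables.get(name)
        if t is not None and col in t.columns:
            vals = pd.to_numeric(t[col], errors="coerce")
            for i in t.index[vals < 0][:50]:
                add(f"{name}.csv", int(i), f"negative {col}")
            if "timestamp" in t.columns and len(t):
                parsed = pd.to_datetime(t["timestamp"], errors="coerce")
                for i in t.index[parsed.isna()][:50]:
                    add(f"{name}.csv", int(i), "unparseable timestamp")
    return diags
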