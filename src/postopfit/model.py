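"""Balanced random forest with leave-one-subject-out cross-validation.

The classifier is an ensemble of decision trees in which every tree is fit on
a *balanced bootstrap*: the majority class is under-sampled (with
replacement) to the minority-class size on each bootstrap draw, so every tree
sees exactly equal class counts. The day-level score is the fraction of trees
voting "abnormal"; a day is called abnormal when that fraction reaches the
vote threshold (ties count as abnormal, favoring sensitivity).

Preprocessing follows the modeling protocol: features with pairwise-complete
Pearson correlation above 0.95 to an already-retained feature are dropped by
a deterministic greedy scan in canonical column order, and remaining missing
values are imputed with the patient's own mean of that feature across their
monitoring period (training-split grand mean as fallback for a patient who
never observed the feature).

Cross-validation is leave-one-subject-out: every fold holds out all days of
one patient. By default pruning and imputation are re-fit inside each fold
from the training patients only; ``paper_faithful=True`` fits them once
globally before splitting instead. The classifier seam (``tree_factory``)
accepts any sklearn-style estimator constructor, so alternative base learners
can be plugged in without changing the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .labeling import LABEL_ABNORMAL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Forest and preprocessing hyper-parameters (defaults are standard
    balanced-random-forest practice; the correlation threshold is part of the
    modeling protocol)."""

    n_trees: int = 100
    max_depth: int | None = None
    features_per_split: str | int = "sqrt"
    vote_threshold: float = 0.5
    corr_threshold: float = 0.95
    seed: int = 0
    paper_faithful: bool = False   # fit prune/impute globally, not per fold

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be a positive integer")
        if not 0.0 < self.vote_threshold < 1.0:
            raise ValueError("vote_threshold must be in (0, 1)")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def prune_correlated(matrix: pd.DataFrame, threshold: float = 0.95
                     ) -> list[str]:
    """Retained feature names after greedy correlation pruning.

    Scans columns in their given (canonical) order; a column is dropped iff
    its pairwise-complete Pearson |r| with any already-retained column
    exceeds ``threshold``. Zero-variance columns have undefined correlation;
    they are retained and flagged.
    """
    corr = matrix.corr(method="pearson")  # pairwise-complete by construction
    zero_var = [c for c in matrix.columns
                if np.isnan(corr.loc[c, c]) or matrix[c].nunique(dropna=True)
                <= 1]
    if zero_var:
        logger.info("zero-variance features retained (correlation "
                    "undefined): %s", zero_var)
    retained: list[str] = []
    for col in matrix.columns:
        if col in zero_var:
            retained.append(col)
            continue
        r = corr.loc[col, [c for c in retained if c not in zero_var]].abs()
        if not (r > threshold).any():
            retained.append(col)
    return retained


def impute_patient_mean(matrix: pd.DataFrame, patient_ids: pd.Series,
                        grand_means: pd.Series | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing cells with the patient's own feature mean.

    A patient with no observed value for a feature falls back to
    ``grand_means`` (computed from ``matrix`` itself when not supplied, i.e.
    on the training split). A feature missing everywhere is dropped with a
    warning. Returns the complete matrix and the grand means used.
    """
    if grand_means is None:
        grand_means = matrix.mean()
    all_missing = [c for c in matrix.columns if np.isnan(grand_means.get(
        c, np.nan)) and matrix[c].isna().all()]
    if all_missing:
        warnings.warn(f"feature(s) with no observed values dropped: "
                      f"{all_missing}")
        matrix = matrix.drop(columns=all_missing)
        grand_means = grand_means.drop(index=all_missing, errors="ignore")
    pm = matrix.groupby(patient_ids.to_numpy()).transform("mean")
    filled = matrix.fillna(pm).fillna(grand_means)
    return filled, grand_means


# ---------------------------------------------------------------------------
# balanced random forest
# ---------------------------------------------------------------------------

def balanced_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices of one balanced bootstrap: n_minority draws with
    replacement from each class (output size 2 * n_minority)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        missing = ({0, 1} - set(classes.tolist())) or {"second class"}
        raise ValueError(f"balanced bootstrap requires both classes; "
                         f"missing {sorted(missing)}")
    n_min = counts.min()
    idx = [rng.choice(np.flatnonzero(y == c), size=n_min, replace=True)
           for c in classes]
    return np.concatenate(idx)


class BalancedRandomForest:
    """Ensemble of decision trees, each on an independent balanced
    bootstrap."""

    def __init__(self, params: ModelParams,
                 tree_factory=DecisionTreeClassifier):
        params.validate()
        self.params = params
        self.tree_factory = tree_factory
        self.trees_: list = []
        self.feature_names_: list[str] | None = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "BalancedRandomForest":
        y = np.asarray(y, dtype=int)
        if (y == 1).sum() < 2:
            raise ValueError("refusing to fit: fewer than 2 abnormal "
                             "training days")
        self.feature_names_ = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        rng = np.random.default_rng(self.params.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.params.n_trees)
        self.trees_ = []
        for s in tree_seeds:
            idx = balanced_bootstrap(y, rng)
            tree = self.tree_factory(
                max_depth=self.params.max_depth,
                max_features=self.params.features_per_split,
                random_state=int(s))
            tree.fit(Xv[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting abnormal, per row."""
        Xv = X[self.feature_names_].to_numpy(dtype=float)
        votes = np.zeros(len(Xv))
        for tree in self.trees_:
            votes += tree.predict(Xv)
        return votes / len(self.trees_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) >= self.params.vote_threshold
                ).astype(int)

    @property
    def feature_importances_(self) -> pd.Series:
        """Mean Gini importance across trees, indexed by feature name."""
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        return pd.Series(imp, index=self.feature_names_)


def train_brf(X: pd.DataFrame, y: np.ndarray, params: ModelParams,
              tree_factory=DecisionTreeClassifier) -> BalancedRandomForest:
    """Fit a balanced random forest (pruning/imputation assumed done)."""
    return BalancedRandomForest(params, tree_factory).fit(X, y)


# ---------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

def loso_cv(dataset: pd.DataFrame, feature_columns: list[str],
            params: ModelParams, tree_factory=DecisionTreeClassifier
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LOSO cross-validated predictions for one modeling table.

    ``dataset`` must carry ``patient_id``, ``pod``, ``label`` and the feature
    columns. One fold per patient; preprocessing (correlation pruning,
    patient-mean imputation) is re-fit from the training patients of each
    fold unless ``params.paper_faithful``, in which case it is fit once on
    the full table. Held-out rows are imputed with the held-out patient's own
    means, falling back to training grand means.

    Returns ``(predictions, importances)``: per-day out-of-fold scores and a
    per-fold feature-importance table (patients x features, NaN where a fold
    did not retain a feature).
    """
    params.validate()
    pids = dataset["patient_id"].unique()
    if len(pids) < 2:
        raise ValueError("LOSO cross-validation requires >= 2 patients")
    y_all = (dataset["label"] == LABEL_ABNORMAL).astype(int).to_numpy()
    X_all = dataset[feature_columns]

    if params.paper_faithful:
        retained_global = prune_correlated(X_all, params.corr_threshold)
        X_global, grand_global = impute_patient_mean(
            X_all[retained_global], dataset["patient_id"])

    fold_seeds = np.random.SeedSequence(params.seed).generate_state(len(pids))
    pred_frames, importance_rows = [], {}
    for fold_id, (pid, fold_seed) in enumerate(zip(pids, fold_seeds)):
        test_mask = (dataset["patient_id"] == pid).to_numpy()
        if not test_mask.any():
            logger.info("fold %s: held-out patient has no included days; "
                        "skipped", pid)
            continue
        train_mask = ~test_mask
        fold_params = params.with_(seed=int(fold_seed % (2**31 - 1)))
        if params.paper_faithful:
            X_train, X_test = X_global[train_mask], X_global[test_mask]
        else:
            retained = prune_correlated(X_all[train_mask],
                                        params.corr_threshold)
            X_train, grand = impute_patient_mean(
                X_all.loc[train_mask, retained],
                dataset.loc[train_mask, "patient_id"])
            X_test, _ = impute_patient_mean(
                X_all.loc[test_mask, X_train.columns],
                dataset.loc[test_mask, "patient_id"], grand_means=grand)
        forest = train_brf(X_train, y_all[train_mask], fold_params,
                           tree_factory)
        scores = forest.predict_scores(X_test)
        pred_frames.append(pd.DataFrame({
            "patient_id": pid,
            "pod": dataset.loc[test_mask, "pod"].to_numpy(),
            "score": scores,
            "predicted": np.where(scores >= params.vote_threshold,
                                  "abnormal", "normal"),
            "fold_id": pid,
        }))
        importance_rows[pid] = forest.feature_importances_

    predictions = pd.concat(pred_frames, ignore_index=True)
    importances = pd.DataFrame(importance_rows).T.reindex(
        columns=feature_columns)
    importances.index.name = "fold_id"
    return predictions, importances
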