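"""One-vs-rest random forests with nested cross-validation.

Each of the four trajectory classes gets its own binary random-forest
classifier trained on the 32 baseline features (baseline severity score
excluded — clustering was based on it, so including it would leak the
label). Hyperparameters are tuned by TPE on the F1 score of the positive
class over inner stratified folds; the outer loop (10 folds x 5 repeats
by default) estimates performance on unseen data. Forests always use 500
trees in the full profile; scaled profiles shrink the forest and budgets,
not the protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    RepeatedKFold,
    RepeatedStratifiedKFold,
    StratifiedKFold,
)

from chftraj.cohort import TRAJECTORY_CLASSES
from chftraj.tpe import TpeResult, tpe_optimize

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "HyperparameterSpace",
    "make_binary_targets",
    "tune_hyperparameters",
    "nested_cv_evaluate",
    "compute_metrics",
    "fit_final_model",
    "PerformanceReport",
]


@dataclass(frozen=True)
class CVPlan:
    """Nested cross-validation layout (defaults follow the full protocol)."""

    outer_folds: int = 10
    outer_repeats: int = 5
    inner_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


def default_param_space() -> dict:
    """Tuned forest hyperparameters and their ranges.

    The split criterion (Gini vs Shannon information gain), class weight,
    maximum depth (unlimited or 2..32), features considered per split
    (sqrt, log2 or a fraction 0.1..1.0) and minimum samples per leaf and
    split are searched; the number of trees is fixed.
    """
    return {
        "criterion": ("categorical", ("gini", "entropy")),
        "class_weight": ("categorical", ("none", "balanced")),
        "max_depth_mode": ("categorical", ("unlimited", "limited")),
        "max_depth": ("int", 2, 32),
        "max_features_mode": ("categorical", ("sqrt", "log2", "fraction")),
        "max_features_frac": ("float", 0.1, 1.0),
        "min_samples_leaf": ("int", 1, 20),
        "min_samples_split": ("int", 2, 20),
    }


@dataclass(frozen=True)
class HyperparameterSpace:
    """Search space plus fixed settings (500 trees, 500 TPE evaluations)."""

    n_trees: int = 500
    n_evaluations: int = 500
    params: dict = field(default_factory=default_param_space)

    def scaled(self, n_trees: int | None = None, n_evaluations: int | None = None):
        return replace(
            self,
            n_trees=self.n_trees if n_trees is None else n_trees,
            n_evaluations=(
                self.n_evaluations if n_evaluations is None else n_evaluations
            ),
        )


def decode_params(raw: dict) -> dict:
    """Translate raw TPE parameters into RandomForestClassifier kwargs."""
    out = {}
    if "criterion" in raw:
        out["criterion"] = raw["criterion"]
    if "class_weight" in raw:
        out["class_weight"] = None if raw["class_weight"] == "none" else raw["class_weight"]
    if "max_depth_mode" in raw:
        out["max_depth"] = (
            None if raw["max_depth_mode"] == "unlimited" else int(raw["max_depth"])
        )
    if "max_features_mode" in raw:
        out["max_features"] = (
            float(raw["max_features_frac"])
            if raw["max_features_mode"] == "fraction"
            else raw["max_features_mode"]
        )
    if "min_samples_leaf" in raw:
        out["min_samples_leaf"] = int(raw["min_samples_leaf"])
    if "min_samples_split" in raw:
        out["min_samples_split"] = int(raw["min_samples_split"])
    return out


def _forest(params: dict, n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        n_jobs=1,
        **decode_params(params),
    )


def make_binary_targets(labels: np.ndarray) -> dict[str, np.ndarray]:
    """One 0/1 indicator vector per trajectory class (one-vs-rest targets)."""
    labels = np.asarray(labels)
    unknown = set(np.unique(labels)) - set(TRAJECTORY_CLASSES)
    if unknown:
        raise ValueError(f"unknown trajectory labels: {sorted(unknown)}")
    return {cls: (labels == cls).astype(int) for cls in TRAJECTORY_CLASSES}


def tune_hyperparameters(
    train_features: np.ndarray,
    train_target: np.ndarray,
    space: HyperparameterSpace,
    inner_folds: int = 5,
    seed: int = 0,
) -> TpeResult:
    """TPE search maximising mean inner-CV F1 of the positive class."""
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training target contains a single class; cannot tune")
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(X, y))

    def objective(params: dict) -> float:
        scores = []
        for tr, va in splits:
            if np.unique(y[tr]).size < 2:
                continue
            clf = _forest(params, space.n_trees, seed)
            clf.fit(X[tr], y[tr])
            scores.append(f1_score(y[va], clf.predict(X[va]), zero_division=0))
        return float(np.mean(scores)) if scores else 0.0

    return tpe_optimize(objective, space.params, space.n_evaluations, seed=seed)


def compute_metrics(y_true, y_pred, y_score=None) -> dict:
    """F1, accuracy, AUPRC, AUROC and the row-normalised confusion matrix.

    F1 is 0 when precision + recall is 0. The confusion matrix is 2x2
    over labels (0, 1), each row divided by its true-label total; a row
    for an absent class is NaN. AUPRC/AUROC require both classes in
    ``y_true`` and a score vector; otherwise they are reported as NaN
    (flagged missing, never coerced to 0).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    counts = np.zeros((2, 2))
    for t, p in zip(y_true, y_pred):
        counts[t, p] += 1
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_tot > 0, counts / row_tot, np.nan)
    out = {
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "normalised_confusion": confusion,
    }
    both = np.unique(y_true).size == 2
    if y_score is not None and both:
        y_score = np.asarray(y_score, dtype=float)
        out["auprc"] = float(average_precision_score(y_true, y_score))
        out["auroc"] = float(roc_auc_score(y_true, y_score))
    else:
        out["auprc"] = np.nan
        out["auroc"] = np.nan
    return out


@dataclass
class PerformanceReport:
    """Per-outer-fold metrics and their aggregate for one binary model."""

    per_fold: pd.DataFrame  # repeat, fold, f1, accuracy, auprc, auroc
    confusion_mean: np.ndarray
    best_params: list
    summary: dict  # metric -> (mean, sd) over outer evaluations
    n_skipped: int
    fold_indices: list  # (train_idx, test_idx) per evaluated fold


def nested_cv_evaluate(
    features: np.ndarray,
    target: np.ndarray,
    plan: CVPlan,
    space: HyperparameterSpace,
) -> PerformanceReport:
    """Nested CV: tune on outer-train via inner folds, score on outer-test.

    Tuning only ever sees outer-train rows; the disjointness of every
    outer test fold from its training fold is asserted here and again in
    the test suite. Outer folds without positives are skipped with a
    logged warning and counted in ``n_skipped``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("target contains a single class")
    cv_cls = RepeatedStratifiedKFold if plan.stratified else RepeatedKFold
    outer = cv_cls(
        n_splits=plan.outer_folds,
        n_repeats=plan.outer_repeats,
        random_state=plan.seed,
    )
    rows, params_log, confusions, indices = [], [], [], []
    n_skipped = 0
    for i, (tr, te) in enumerate(outer.split(X, y)):
        repeat, fold = divmod(i, plan.outer_folds)
        assert np.intersect1d(tr, te).size == 0
        if y[te].sum() == 0 or np.unique(y[tr]).size < 2:
            logger.warning(
                "outer fold %d (repeat %d) skipped: positives absent", fold, repeat
            )
            n_skipped += 1
            continue
        tuned = tune_hyperparameters(
            X[tr], y[tr], space, inner_folds=plan.inner_folds, seed=plan.seed + i
        )
        clf = _forest(tuned.best_params, space.n_trees, plan.seed + i)
        clf.fit(X[tr], y[tr])
        score = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        m = compute_metrics(y[te], clf.predict(X[te]), score)
        rows.append(
            {
                "repeat": repeat,
                "fold": fold,
                "f1": m["f1"],
                "accuracy": m["accuracy"],
                "auprc": m["auprc"],
                "auroc": m["auroc"],
            }
        )
        confusions.append(m["normalised_confusion"])
        params_log.append(tuned.best_params)
        indices.append((tr, te))
    per_fold = pd.DataFrame(rows)
    summary = {
        metric: (float(per_fold[metric].mean()), float(per_fold[metric].std(ddof=1)))
        for metric in ("f1", "accuracy", "auprc", "auroc")
    }
    return PerformanceReport(
        per_fold=per_fold,
        confusion_mean=np.nanmean(np.stack(confusions), axis=0),
        best_params=params_log,
        summary=summary,
        n_skipped=n_skipped,
        fold_indices=indices,
    )


def fit_final_model(
    features: np.ndarray,
    target: np.ndarray,
    best_params: dict,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Refit one forest on all rows with tuned parameters (for attribution)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("target contains a single class")
    clf = _forest(best_params, n_trees, seed)
    clf.fit(X, y)
    return clf
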