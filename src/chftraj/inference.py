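"""Permutation-null significance testing with BH-FDR control.

Whether each one-vs-rest model predicts better than chance, and whether
each feature contributes more than chance, is judged against empirical
null distributions: the four-class label vector is shuffled once per
draw (outside the cross-validation framework), cross-validated F1 and
full-data-refit feature importances are recomputed with the tuned
hyperparameters frozen (no re-tuning inside the null), and one-sided
p-values count null draws at or above the observed statistic with the
add-one convention p = (1 + #{null >= true}) / (B + 1). Benjamini-
Hochberg FDR correction is applied separately to the performance family
(4 tests) and the importance family (4 x n_features tests).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests

from chftraj.classifier import CVPlan, _forest, compute_metrics, make_binary_targets
from chftraj.cohort import TRAJECTORY_CLASSES
from chftraj.explain import impurity_importance

__all__ = [
    "NullSet",
    "FdrResult",
    "params_checksum",
    "permuted_run",
    "build_null",
    "one_sided_p",
    "bh_fdr",
    "run_inference",
]


def params_checksum(frozen_params: dict) -> str:
    """Stable digest of the per-class hyperparameter sets used in a draw."""
    canon = repr(sorted((c, sorted(p.items())) for c, p in frozen_params.items()))
    return hashlib.sha256(canon.encode()).hexdigest()


def _cv_f1(X, y, params: dict, plan: CVPlan, n_trees: int, seed: int) -> float:
    """Mean outer-CV F1 with fixed hyperparameters (no tuning)."""
    cv_cls = RepeatedStratifiedKFold if plan.stratified else RepeatedKFold
    outer = cv_cls(
        n_splits=plan.outer_folds, n_repeats=plan.outer_repeats, random_state=seed
    )
    scores = []
    for tr, te in outer.split(X, y):
        if np.unique(y[tr]).size < 2 or y[te].sum() == 0:
            continue
        clf = _forest(params, n_trees, seed)
        clf.fit(X[tr], y[tr])
        scores.append(compute_metrics(y[te], clf.predict(X[te]))["f1"])
    return float(np.mean(scores)) if scores else np.nan


def permuted_run(
    features: np.ndarray,
    labels: np.ndarray,
    frozen_params: dict,
    plan: CVPlan,
    seed: int,
    n_trees: int = 500,
    statistics: tuple = ("f1", "importance"),
) -> tuple[dict, dict, str]:
    """One null draw: shuffle labels, recompute F1 and importances.

    ``frozen_params`` maps each trajectory class to the hyperparameters
    tuned on the real labels; re-tuning inside the null is not allowed,
    so missing parameters are an error. Returns per-class F1 draws,
    per-class importance-vector draws, and the checksum of the parameter
    sets actually used. ``statistics`` restricts the draw to a subset of
    {"f1", "importance"} when only one null family is needed.
    """
    if not frozen_params:
        raise ValueError(
            "frozen_params is required: the permutation null must reuse the "
            "hyperparameters tuned on the real labels, never re-tune"
        )
    missing = [c for c in TRAJECTORY_CLASSES if c not in frozen_params]
    if missing:
        raise ValueError(f"frozen_params missing classes: {missing}")
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    shuffled = np.asarray(labels)[rng.permutation(len(labels))]
    targets = make_binary_targets(shuffled)
    f1_draw, imp_draw = {}, {}
    for cls in TRAJECTORY_CLASSES:
        y = targets[cls]
        params = frozen_params[cls]
        if "f1" in statistics:
            f1_draw[cls] = _cv_f1(X, y, params, plan, n_trees, seed)
        if "importance" in statistics:
            clf = _forest(params, n_trees, seed)
            clf.fit(X, y)
            imp_draw[cls] = impurity_importance(clf).normalised
    return f1_draw, imp_draw, params_checksum(frozen_params)


@dataclass
class NullSet:
    """B permutation draws of F1 and importance per trajectory class."""

    f1: dict                # class -> (B,) array
    importance: dict        # class -> (B, p) array
    B: int
    seed: int
    params_checksums: list  # one digest per draw; all must be identical

    def frozen(self) -> bool:
        return len(set(self.params_checksums)) == 1


def build_null(
    features: np.ndarray,
    labels: np.ndarray,
    frozen_params: dict,
    plan: CVPlan,
    B: int = 1000,
    seed: int = 0,
    n_trees: int = 500,
    statistics: tuple = ("f1", "importance"),
) -> NullSet:
    """Assemble the full permutation null from B independent draws."""
    f1 = {c: np.empty(B) for c in TRAJECTORY_CLASSES}
    imp = {c: [] for c in TRAJECTORY_CLASSES}
    checksums = []
    for b in range(B):
        f1_d, imp_d, digest = permuted_run(
            features, labels, frozen_params, plan, seed=seed + b,
            n_trees=n_trees, statistics=statistics,
        )
        for c in TRAJECTORY_CLASSES:
            if "f1" in statistics:
                f1[c][b] = f1_d[c]
            if "importance" in statistics:
                imp[c].append(imp_d[c])
        checksums.append(digest)
    return NullSet(
        f1=f1 if "f1" in statistics else {},
        importance=(
            {c: np.vstack(v) for c, v in imp.items()}
            if "importance" in statistics
            else {}
        ),
        B=B,
        seed=seed,
        params_checksums=checksums,
    )


def one_sided_p(true_value: float, null_values: np.ndarray) -> float:
    """Add-one permutation p-value; ties count against the alternative."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null distribution")
    exceed = int(np.sum(null_values >= true_value))
    return (1 + exceed) / (null_values.size + 1)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FdrResult:
    family: str
    table: pd.DataFrame
    alpha: float


def run_inference(
    real_f1: dict,
    real_importance: dict,
    nulls: NullSet,
    feature_names: list,
    alpha: float = 0.05,
) -> tuple[FdrResult, FdrResult]:
    """p/q values for the performance family and the importance family.

    The two families (4 F1 tests; 4 x n_features importance tests) are
    corrected independently. Family shapes are validated against the
    four-class design and the feature list before any p-value is formed.
    """
    p = len(feature_names)
    for name, d in (("real_f1", real_f1), ("real_importance", real_importance),
                    ("null f1", nulls.f1), ("null importance", nulls.importance)):
        if set(d) != set(TRAJECTORY_CLASSES):
            raise ValueError(f"{name} classes {sorted(d)} do not match the "
                             f"4-class design")
    for c in TRAJECTORY_CLASSES:
        if np.asarray(real_importance[c]).size != p:
            raise ValueError(
                f"importance vector for {c} has "
                f"{np.asarray(real_importance[c]).size} entries, expected {p}"
            )
        if nulls.importance[c].shape[1] != p:
            raise ValueError(f"null importance for {c} has wrong width")
    if not nulls.frozen():
        raise ValueError("null draws used differing hyperparameters; the null "
                         "must be generated with frozen tuned parameters")

    perf_rows = []
    for c in TRAJECTORY_CLASSES:
        perf_rows.append(
            {"class": c, "f1": real_f1[c],
             "p": one_sided_p(real_f1[c], nulls.f1[c])}
        )
    perf = pd.DataFrame(perf_rows)
    perf["q"] = bh_fdr(perf["p"].to_numpy())
    perf["significant"] = perf["q"] <= alpha

    imp_rows = []
    for c in TRAJECTORY_CLASSES:
        real = np.asarray(real_importance[c], dtype=float)
        null = nulls.importance[c]
        for j, feat in enumerate(feature_names):
            imp_rows.append(
                {
                    "class": c,
                    "feature": feat,
                    "importance": real[j],
                    "p": one_sided_p(real[j], null[:, j]),
                }
            )
    imp = pd.DataFrame(imp_rows)
    imp["q"] = bh_fdr(imp["p"].to_numpy())
    imp["significant"] = imp["q"] <= alpha

    return (
        FdrResult("performance", perf, alpha),
        FdrResult("importance", imp, alpha),
    )
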