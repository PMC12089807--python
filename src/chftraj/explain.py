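"""Feature importance and directional SHAP summaries for one-vs-rest models.

Two complementary views of each binary forest: impurity-based importance
(how much a feature reduces label uncertainty, averaged over trees) ranks
features but carries no direction; per-prediction SHAP attributions add
the direction, and a rank correlation between feature values and their
attributions summarises each feature as risk-like (positive), protective
(negative) or mixed for the class in question.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from chftraj.treeshap import tree_shap_values

__all__ = [
    "ImportanceVector",
    "ShapMatrix",
    "DirectionSummary",
    "impurity_importance",
    "shap_attributions",
    "direction_summary",
]

#: |Spearman rho| below which a feature's direction is called "mixed"
SIGN_THRESHOLD = 0.1


@dataclass
class ImportanceVector:
    feature_names: list
    raw: np.ndarray         # mean over trees of total weighted impurity decrease
    normalised: np.ndarray  # raw scaled to sum to 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "importance_raw": self.raw,
                "importance": self.normalised,
            }
        )


@dataclass
class ShapMatrix:
    """Per-sample, per-feature attributions for one one-vs-rest model."""

    values: np.ndarray  # n x p
    base_value: float
    feature_names: list
    class_label: str | None = None

    def check_additivity(self, model, X, atol: float = 1e-6) -> None:
        """Assert base value + row sums equal the model's predicted score."""
        pred = model.predict_proba(np.asarray(X, dtype=float))[:, -1]
        gap = np.abs(self.base_value + self.values.sum(axis=1) - pred)
        if gap.max() > atol:
            raise AssertionError(f"SHAP additivity violated: max gap {gap.max():.3g}")


@dataclass
class DirectionSummary:
    table: pd.DataFrame  # feature, rho, sign, flagged

    def sign_of(self, feature: str) -> str:
        return self.table.set_index("feature").loc[feature, "sign"]


def _feature_names(model, features) -> list:
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
    else:
        names = [f"feature_{i}" for i in range(np.asarray(features).shape[1])]
    trained = getattr(model, "feature_names_in_", None)
    if trained is not None and isinstance(features, pd.DataFrame):
        if list(trained) != names:
            raise ValueError(
                "feature columns do not match the model's training schema: "
                f"expected {list(trained)}, got {names}"
            )
    return names


def impurity_importance(forest, feature_names=None) -> ImportanceVector:
    """Mean over trees of each feature's total weighted impurity decrease.

    A feature that is constant (never chosen for a split) has importance
    exactly 0. The normalised variant divides by the total so values sum
    to 1; if no split was made anywhere the normalised vector is all 0.
    """
    try:
        check_is_fitted(forest)
    except NotFittedError as exc:
        raise ValueError("forest must be fitted before computing importance") from exc
    raw = np.mean(
        [est.tree_.compute_feature_importances(normalize=False)
         for est in forest.estimators_],
        axis=0,
    )
    total = raw.sum()
    normalised = raw / total if total > 0 else np.zeros_like(raw)
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(raw.size)]
    return ImportanceVector(list(feature_names), raw, normalised)


def shap_attributions(model, features, class_label: str | None = None) -> ShapMatrix:
    """Tree-SHAP attribution matrix for ``model`` over ``features``.

    The explained output is the positive-class probability; the base
    value is the model's cover-weighted mean output, so for every sample
    base value + attributions = predicted score.
    """
    names = _feature_names(model, features)
    X = np.asarray(features, dtype=float)
    values, base = tree_shap_values(model, X)
    return ShapMatrix(values=values, base_value=base,
                      feature_names=names, class_label=class_label)


def direction_summary(shap: ShapMatrix, features) -> DirectionSummary:
    """Sign call per feature from rank correlation of value vs attribution.

    rho = Spearman correlation between the feature column and its SHAP
    column; sign is "positive"/"negative" when |rho| >= 0.1, otherwise
    "mixed". Zero-variance attribution columns (feature never influences
    the model) are flagged and called "mixed".
    """
    X = np.asarray(features, dtype=float)
    if X.shape != shap.values.shape:
        raise ValueError("features and attribution matrix shapes differ")
    rows = []
    for j, name in enumerate(shap.feature_names):
        col = shap.values[:, j]
        if np.ptp(col) == 0 or np.ptp(X[:, j]) == 0:
            rows.append({"feature": name, "rho": np.nan, "sign": "mixed",
                         "flagged": True})
            continue
        rho = spearmanr(X[:, j], col).statistic
        if not np.isfinite(rho) or abs(rho) < SIGN_THRESHOLD:
            sign = "mixed"
        else:
            sign = "positive" if rho > 0 else "negative"
        rows.append({"feature": name, "rho": rho, "sign": sign, "flagged": False})
    return DirectionSummary(pd.DataFrame(rows))
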