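"""Exact SHAP values for decision-tree ensembles.

Implements the path-dependent polynomial-time tree-SHAP recursion: for
every path through a tree it tracks, for each feature on the path, the
fraction of coalitions in which the feature is "present" (follows the
data point) versus "absent" (splits weighted by the node cover
fractions), and accumulates each feature's Shapley weight in one
traversal. Cost is O(leaves x depth^2) per sample and tree, and the
result equals brute-force Shapley enumeration over feature coalitions
with cover-weighted conditional expectations.

For a random-forest classifier the explained output is the positive-class
probability (the forest's vote fraction), which is the mean of the
per-tree leaf probabilities, so forest SHAP values are the mean of
per-tree SHAP values and the base value is the cover-weighted mean leaf
value averaged over trees. Local additivity (base value + attributions =
predicted score) holds to numerical precision for every sample.

The inner recursion is numba-compiled; the first call in a session pays
a one-off compilation cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = ["tree_shap_values", "expected_value"]


@njit(cache=False)
def _extend(fi, zf, of, pw, off, unique_depth, pz, po, pidx):
    fi[off + unique_depth] = pidx
    zf[off + unique_depth] = pz
    of[off + unique_depth] = po
    pw[off + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[off + i + 1] += po * pw[off + i] * (i + 1) / (unique_depth + 1)
        pw[off + i] = pz * pw[off + i] * (unique_depth - i) / (unique_depth + 1)


@njit(cache=False)
def _unwind(fi, zf, of, pw, off, unique_depth, path_index):
    one = of[off + path_index]
    zero = zf[off + path_index]
    nxt = pw[off + unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[off + i]
            pw[off + i] = nxt * (unique_depth + 1) / ((i + 1) * one)
            nxt = tmp - pw[off + i] * zero * (unique_depth - i) / (unique_depth + 1)
        else:
            pw[off + i] = pw[off + i] * (unique_depth + 1) / (
                zero * (unique_depth - i)
            )
    for i in range(path_index, unique_depth):
        fi[off + i] = fi[off + i + 1]
        zf[off + i] = zf[off + i + 1]
        of[off + i] = of[off + i + 1]


@njit(cache=False)
def _unwound_sum(zf, of, pw, off, unique_depth, path_index):
    one = of[off + path_index]
    zero = zf[off + path_index]
    nxt = pw[off + unique_depth]
    total = 0.0
    if one != 0.0:
        for i in range(unique_depth - 1, -1, -1):
            tmp = nxt / ((i + 1) * one)
            total += tmp
            nxt = pw[off + i] - tmp * zero * (unique_depth - i)
    else:
        for i in range(unique_depth - 1, -1, -1):
            total += pw[off + i] / (zero * (unique_depth - i))
    return total * (unique_depth + 1)


@njit(cache=False)
def _recurse_impl(
    left, right, feature, threshold, cover, values, x, phi,
    fi, zf, of, pw, parent_off, node, unique_depth, pz, po, pidx,
):
    off = parent_off + unique_depth + 1
    for i in range(unique_depth + 1):
        fi[off + i] = fi[parent_off + i]
        zf[off + i] = zf[parent_off + i]
        of[off + i] = of[parent_off + i]
        pw[off + i] = pw[parent_off + i]
    _extend(fi, zf, of, pw, off, unique_depth, pz, po, pidx)

    if left[node] < 0:  # leaf
        for i in range(1, unique_depth + 1):
            w = _unwound_sum(zf, of, pw, off, unique_depth, i)
            phi[fi[off + i]] += w * (of[off + i] - zf[off + i]) * values[node]
        return

    f = feature[node]
    if x[f] <= threshold[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    hot_zero = cover[hot] / cover[node]
    cold_zero = cover[cold] / cover[node]
    inc_zero = 1.0
    inc_one = 1.0
    path_index = unique_depth + 1
    for i in range(unique_depth + 1):
        if fi[off + i] == f:
            path_index = i
            break
    depth = unique_depth
    if path_index <= unique_depth:
        inc_zero = zf[off + path_index]
        inc_one = of[off + path_index]
        _unwind(fi, zf, of, pw, off, depth, path_index)
        depth -= 1
    _recurse_impl(
        left, right, feature, threshold, cover, values, x, phi,
        fi, zf, of, pw, off, hot, depth + 1, hot_zero * inc_zero, inc_one, f,
    )
    _recurse_impl(
        left, right, feature, threshold, cover, values, x, phi,
        fi, zf, of, pw, off, cold, depth + 1, cold_zero * inc_zero, 0.0, f,
    )


@njit(cache=False)
def _single_tree_shap(left, right, feature, threshold, cover, values, X, out):
    n, m = X.shape
    # depth bound: longest root-leaf path
    max_depth = 0
    depth = np.zeros(left.shape[0], dtype=np.int64)
    for node in range(left.shape[0]):
        if left[node] >= 0:
            depth[left[node]] = depth[node] + 1
            depth[right[node]] = depth[node] + 1
        if depth[node] > max_depth:
            max_depth = depth[node]
    s = (max_depth + 2) * (max_depth + 3) // 2 + max_depth + 3
    fi = np.empty(s, dtype=np.int64)
    zf = np.empty(s)
    of = np.empty(s)
    pw = np.empty(s)
    for r in range(n):
        phi = np.zeros(m)
        _recurse_impl(
            left, right, feature, threshold, cover, values, X[r], phi,
            fi, zf, of, pw, -1, 0, 0, 1.0, 1.0, -1,
        )
        out[r] += phi


def _node_values(tree, class_index: int | None) -> np.ndarray:
    """Per-node scalar output: class probability or regression value."""
    v = tree.tree_.value  # (n_nodes, 1, n_outputs_or_classes)
    if class_index is None:
        return np.ascontiguousarray(v[:, 0, 0], dtype=float)
    row = v[:, 0, :]
    totals = row.sum(axis=1, keepdims=True)
    return np.ascontiguousarray((row / totals)[:, class_index], dtype=float)


def _trees_and_class(model):
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        trees = model.estimators_
    elif isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        trees = [model]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if isinstance(model, (RandomForestClassifier, DecisionTreeClassifier)):
        classes = list(model.classes_)
        if len(classes) != 2:
            raise ValueError("only binary classifiers are supported")
        return trees, len(classes) - 1  # classes_ is sorted; positive = last
    return trees, None


def expected_value(model) -> float:
    """Cover-weighted mean output (the SHAP base value) of the model."""
    trees, class_index = _trees_and_class(model)
    total = 0.0
    for est in trees:
        t = est.tree_
        vals = _node_values(est, class_index)
        leaves = t.children_left < 0
        cov = t.weighted_n_node_samples
        total += float((cov[leaves] * vals[leaves]).sum() / cov[0])
    return total / len(trees)


def tree_shap_values(model, X) -> tuple[np.ndarray, float]:
    """SHAP attribution matrix (n x p) and base value for ``model`` on ``X``.

    For binary classifiers the explained output is the predicted
    probability of the positive (larger) class label.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    trees, class_index = _trees_and_class(model)
    n_feat = trees[0].tree_.n_features
    if X.shape[1] != n_feat:
        raise ValueError(
            f"X has {X.shape[1]} features but the model was trained on {n_feat}"
        )
    out = np.zeros_like(X)
    for est in trees:
        t = est.tree_
        _single_tree_shap(
            t.children_left.astype(np.int64),
            t.children_right.astype(np.int64),
            t.feature.astype(np.int64),
            t.threshold.astype(np.float64),
            t.weighted_n_node_samples.astype(np.float64),
            _node_values(est, class_index),
            X,
            out,
        )
    out /= len(trees)
    return out, expected_value(model)
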