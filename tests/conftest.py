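"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (quadratic loops, exhaustive
coalition enumeration) and independent of the package's implementations:
they define what the fast code must reproduce.
"""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from chftraj import default_config, generate_cohort
from chftraj.cohort import feature_columns


def brute_silhouette(values, labels):
    """O(n^2) silhouette from first principles (1-D absolute distance)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([abs(values[i] - values[j]) for j in same])
        b = np.inf
        for lab in set(labels.tolist()) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == lab]
            b = min(b, np.mean([abs(values[i] - values[j]) for j in others]))
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def tree_conditional_expectation(tree, x, coalition, class_index=None):
    """Cover-weighted conditional expectation E[f(x) | features in coalition]."""
    t = tree.tree_
    if class_index is None:
        vals = t.value[:, 0, 0]
    else:
        row = t.value[:, 0, :]
        vals = row[:, class_index] / row.sum(axis=1)
    cov = t.weighted_n_node_samples

    def rec(node):
        if t.children_left[node] < 0:
            return vals[node]
        f = t.feature[node]
        left, right = t.children_left[node], t.children_right[node]
        if f in coalition:
            return rec(left if x[f] <= t.threshold[node] else right)
        return (cov[left] * rec(left) + cov[right] * rec(right)) / cov[node]

    return rec(0)


def brute_shapley(tree, x, n_features, class_index=None):
    """Exact Shapley values by enumeration over all feature coalitions."""
    phi = np.zeros(n_features)
    feats = list(range(n_features))
    for i in feats:
        others = [f for f in feats if f != i]
        for k in range(n_features):
            for S in combinations(others, k):
                w = factorial(k) * factorial(n_features - 1 - k) / factorial(n_features)
                with_i = tree_conditional_expectation(
                    tree, x, set(S) | {i}, class_index
                )
                without_i = tree_conditional_expectation(tree, x, set(S), class_index)
                phi[i] += w * (with_i - without_i)
    return phi


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure synthetic cohort at n=300 (one seed, reused)."""
    return generate_cohort(default_config(n_participants=300, seed=7))


@pytest.fixture(scope="session")
def small_cohort_X(small_cohort):
    return small_cohort[feature_columns(small_cohort)].to_numpy(dtype=float)
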