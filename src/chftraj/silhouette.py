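"""Silhouette score for crisp 1-D partitions.

Distance is absolute difference (Euclidean in one dimension). For point i
with intra-cluster mean distance a(i) (excluding self) and b(i) the
smallest mean distance to another cluster, s(i) = (b - a) / max(a, b).
Points in singleton clusters contribute s = 0, as do points where
max(a, b) = 0 (coincident point masses).
"""

from __future__ import annotations

import numpy as np


def silhouette_samples(values: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Per-point silhouette widths for a hard 1-D clustering."""
    x = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(assignments).ravel()
    if x.shape != labels.shape:
        raise ValueError("values and assignments must have the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("silhouette is undefined for a single cluster")

    n = x.size
    sizes = np.bincount(inv, minlength=k)
    # mean distance from every point to every cluster: n x k
    dist = np.abs(x[:, None] - x[None, :])
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = dist[:, inv == c].sum(axis=1)
    mean_to = sums / sizes[None, :]

    own = inv
    own_size = sizes[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        # exclude self-distance (0) from the intra-cluster mean
        a = np.where(own_size > 1, sums[np.arange(n), own] / (own_size - 1), 0.0)
    other = mean_to.copy()
    other[np.arange(n), own] = np.inf
    b = other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = (own_size > 1) & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return s


def silhouette_score(values: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette width over all points.

    Raises ``ValueError`` when fewer than two clusters are present.
    """
    return float(silhouette_samples(values, assignments).mean())
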