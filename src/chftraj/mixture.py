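"""Univariate Gaussian-mixture trajectory clustering.

Severity scores at each timepoint are modelled as a k-component normal
mixture fitted by expectation-maximisation. The number of components is
chosen over a candidate range by the silhouette score of the hard
(argmax-responsibility) partition, with log-likelihood, AIC and BIC
recorded per k as a diagnostic table. Components are then ordered by mean
severity, the lowest-severity cluster is labelled "low" and all others
"high" (at follow-up this merges the moderate and severe clusters), and
the low/high pair at the two timepoints defines one of four trajectory
classes per participant.

EM details: k-means-style seeding on quantile-spread initial means with
multiple restarts (univariate EM is multimodal), convergence on absolute
log-likelihood improvement < tol, and a variance floor of 1e-4 x the
sample variance to keep spike components from collapsing onto single
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from chftraj.cohort import TRAJECTORY_CLASSES
from chftraj.silhouette import silhouette_score

__all__ = [
    "DegeneracyError",
    "MixtureFit",
    "ClusterSolution",
    "fit_univariate_gmm",
    "select_k",
    "order_by_severity",
    "binarize_severity",
    "derive_trajectory_labels",
    "information_criteria",
]


class DegeneracyError(ValueError):
    """The data cannot support the requested number of components."""


@dataclass
class MixtureFit:
    """Parameters and per-observation responsibilities of a fitted mixture."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    responsibilities: np.ndarray
    n_iterations: int
    converged: bool
    ll_trace: np.ndarray

    def hard_assignments(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)


@dataclass
class ClusterSolution:
    """A selected clustering with its per-k diagnostics.

    ``diagnostics`` has one row per candidate k (k, silhouette,
    log_likelihood, aic, bic, converged); ``severity_order`` maps
    component index -> severity rank (0 = lowest mean).
    """

    k_selected: int
    assignments: np.ndarray
    silhouette: float
    fit: MixtureFit
    diagnostics: pd.DataFrame
    severity_order: np.ndarray
    failures: dict = field(default_factory=dict)


@njit(cache=False)
def _em_core(xu, counts, means0, var0, tol, max_iter, var_floor):
    """Weighted EM over unique values with multiplicities (numba kernel).

    Returns (weights, means, variances, ll_trace, responsibilities,
    n_iterations, converged, died). ``died`` marks a collapsed component
    (effective count ~ 0); the caller discards such restarts.
    """
    m = xu.size
    k = means0.size
    n = counts.sum()
    weights = np.full(k, 1.0 / k)
    means = means0.copy()
    variances = np.full(k, var0 if var0 > var_floor else var_floor)
    trace = np.empty(max_iter)
    resp = np.zeros((m, k))
    prev_ll = -1e300
    converged = False
    it = 0
    log2pi = np.log(2.0 * np.pi)
    for it in range(1, max_iter + 1):
        ll = 0.0
        for i in range(m):
            mx = -1e300
            for j in range(k):
                lp = (
                    np.log(weights[j])
                    - 0.5 * (log2pi + np.log(variances[j]))
                    - 0.5 * (xu[i] - means[j]) ** 2 / variances[j]
                )
                resp[i, j] = lp
                if lp > mx:
                    mx = lp
            s = 0.0
            for j in range(k):
                s += np.exp(resp[i, j] - mx)
            lse = mx + np.log(s)
            ll += counts[i] * lse
            for j in range(k):
                resp[i, j] = np.exp(resp[i, j] - lse)
        trace[it - 1] = ll
        if ll - prev_ll < tol and prev_ll > -1e299:
            converged = True
            break
        prev_ll = ll
        for j in range(k):
            nj = 0.0
            mu = 0.0
            for i in range(m):
                c = counts[i] * resp[i, j]
                nj += c
                mu += c * xu[i]
            if nj < 1e-10:
                return weights, means, variances, trace[:it], resp, it, False, True
            mu /= nj
            v = 0.0
            for i in range(m):
                v += counts[i] * resp[i, j] * (xu[i] - mu) ** 2
            v /= nj
            if v < var_floor:
                v = var_floor
            weights[j] = nj / n
            means[j] = mu
            variances[j] = v
    return weights, means, variances, trace[:it], resp, it, converged, False


def _em_once(
    xu: np.ndarray,
    counts: np.ndarray,
    means0: np.ndarray,
    var0: float,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> MixtureFit | None:
    """One EM run on the unique-value representation of the data.

    Integer severity scores repeat heavily, so running EM on the unique
    values (weighting by count) is exact and much faster than iterating
    over participants; responsibilities are expanded by the caller.
    """
    weights, means, variances, trace, resp, it, converged, died = _em_core(
        xu, counts, means0, var0, tol, max_iter, var_floor
    )
    if died:
        return None
    return MixtureFit(
        k=means0.size,
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood=float(trace[-1]),
        responsibilities=resp.copy(),
        n_iterations=it,
        converged=converged,
        ll_trace=trace.copy(),
    )


def fit_univariate_gmm(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> MixtureFit:
    """Fit a k-component univariate normal mixture by EM.

    The best of ``n_restarts`` runs (by final log-likelihood) is returned.
    The first restart starts from unjittered quantile-spread means, the
    rest jitter the starting means; all runs share the seeded generator.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(x).size
    if distinct < k:
        raise DegeneracyError(
            f"only {distinct} distinct values for {k} components; "
            "the mixture is degenerate"
        )
    sample_var = float(np.var(x))
    if sample_var == 0.0 and k > 1:
        raise DegeneracyError("zero-variance input cannot support k > 1")

    if k == 1:  # closed-form MLE
        mean = float(np.mean(x))
        var = max(sample_var, 1e-12)
        ll = float(
            -0.5 * x.size * np.log(2 * np.pi * var)
            - np.sum((x - mean) ** 2) / (2 * var)
        )
        return MixtureFit(
            k=1,
            weights=np.array([1.0]),
            means=np.array([mean]),
            variances=np.array([var]),
            log_likelihood=ll,
            responsibilities=np.ones((x.size, 1)),
            n_iterations=1,
            converged=True,
            ll_trace=np.array([ll]),
        )

    rng = np.random.default_rng(seed)
    var_floor = 1e-4 * sample_var
    quantile_means = np.quantile(x, (np.arange(k) + 0.5) / k)
    sd = np.sqrt(sample_var)
    xu, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    best: MixtureFit | None = None
    for r in range(n_restarts):
        means0 = quantile_means.copy()
        if r > 0:
            means0 = means0 + rng.normal(0.0, 0.25 * sd / k, size=k)
        fit = _em_once(
            xu, counts.astype(float), means0, sample_var / k, tol, max_iter,
            var_floor,
        )
        if fit is None:
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise DegeneracyError(
            f"all {n_restarts} EM restarts collapsed for k={k}"
        )
    best.responsibilities = best.responsibilities[inverse]
    return best


def information_criteria(fit: MixtureFit, n: int) -> tuple[float, float]:
    """AIC and BIC with p = 3k - 1 free parameters (k weights sum to 1)."""
    p = 3 * fit.k - 1
    aic = 2.0 * p - 2.0 * fit.log_likelihood
    bic = p * np.log(n) - 2.0 * fit.log_likelihood
    return float(aic), float(bic)


def order_by_severity(fit: MixtureFit) -> np.ndarray:
    """Map component index -> severity rank (0 = lowest mean).

    Equal means are broken by ascending variance (tighter component
    ranked less severe), then by index for full determinism.
    """
    order = np.lexsort((np.arange(fit.k), fit.variances, fit.means))
    ranks = np.empty(fit.k, dtype=int)
    ranks[order] = np.arange(fit.k)
    return ranks


def select_k(
    values: np.ndarray,
    k_range=range(2, 13),
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
) -> ClusterSolution:
    """Fit every k in ``k_range`` and keep the highest-silhouette solution.

    Ties in silhouette go to the smallest k (parsimony). Candidate fits
    that are degenerate are recorded in ``failures`` and skipped; if every
    candidate fails the error lists all per-k failures.
    """
    x = np.asarray(values, dtype=float).ravel()
    rows = []
    failures: dict[int, str] = {}
    best = None  # (silhouette, k, fit, assignments)
    for k in k_range:
        try:
            fit = fit_univariate_gmm(
                x, k, seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
            )
            labels = fit.hard_assignments()
            if np.unique(labels).size < 2:
                raise DegeneracyError(
                    f"hard assignment collapsed to one cluster at k={k}"
                )
            sil = silhouette_score(x, labels)
        except (DegeneracyError, ValueError) as exc:
            failures[k] = str(exc)
            continue
        aic, bic = information_criteria(fit, x.size)
        rows.append(
            {
                "k": k,
                "silhouette": sil,
                "log_likelihood": fit.log_likelihood,
                "aic": aic,
                "bic": bic,
                "converged": fit.converged,
            }
        )
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, fit, labels)
    if best is None:
        detail = "; ".join(f"k={k}: {msg}" for k, msg in failures.items())
        raise DegeneracyError(f"no candidate k produced a valid clustering ({detail})")
    sil, k_sel, fit, labels = best
    return ClusterSolution(
        k_selected=k_sel,
        assignments=labels,
        silhouette=sil,
        fit=fit,
        diagnostics=pd.DataFrame(rows),
        severity_order=order_by_severity(fit),
        failures=failures,
    )


def binarize_severity(solution: ClusterSolution, low_ranks=(0,)) -> np.ndarray:
    """Collapse clusters to "low"/"high" severity per participant.

    By default only the lowest-severity cluster (rank 0) maps to "low";
    every other cluster maps to "high" — at follow-up this merges the
    moderate and severe clusters under a single label.
    """
    ranks = solution.severity_order[solution.assignments]
    return np.where(np.isin(ranks, low_ranks), "low", "high")


def derive_trajectory_labels(
    baseline_bin: np.ndarray, followup_bin: np.ndarray
) -> np.ndarray:
    """Four trajectory classes from low/high severity at the two timepoints.

    (low, low) -> good_prognosis; (high, low) -> remitting_course;
    (low, high) -> clinical_worsening; (high, high) -> persistent_course.
    """
    b = np.asarray(baseline_bin)
    f = np.asarray(followup_bin)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up vectors differ in length")
    bad = set(np.unique(b)) | set(np.unique(f))
    if not bad <= {"low", "high"}:
        raise ValueError(f"severity labels must be 'low'/'high', got {sorted(bad)}")
    labels = np.empty(b.shape, dtype=object)
    labels[(b == "low") & (f == "low")] = TRAJECTORY_CLASSES[0]
    labels[(b == "high") & (f == "low")] = TRAJECTORY_CLASSES[1]
    labels[(b == "low") & (f == "high")] = TRAJECTORY_CLASSES[2]
    labels[(b == "high") & (f == "high")] = TRAJECTORY_CLASSES[3]
    return labels
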