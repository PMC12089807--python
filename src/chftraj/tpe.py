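"""Sequential hyperparameter search with a tree-structured Parzen estimator.

The optimiser maximises a black-box objective over a dictionary-shaped
search space. It follows the standard TPE recipe: a block of random
startup evaluations, then, at each step, completed trials are split into
a "good" fraction (top gamma by score) and the rest, one-dimensional
Parzen density estimates l(x) and g(x) are built per parameter from the
good and bad observations, candidates are sampled from l and the one
maximising the density ratio l(x)/g(x) is evaluated next.

Space specification (per parameter name):

* ``("categorical", (choice, ...))``
* ``("int", lo, hi)``    — inclusive bounds
* ``("float", lo, hi)``

All randomness flows through one seeded generator, so a run is fully
reproducible; a space collapsed to a single point is evaluated exactly
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TpeResult", "tpe_optimize", "sample_random"]


@dataclass
class TpeResult:
    best_params: dict
    best_score: float
    trials: pd.DataFrame  # one row per evaluation: parameters + "score"


def _is_singleton(space: dict) -> bool:
    for spec in space.values():
        kind = spec[0]
        if kind == "categorical" and len(spec[1]) > 1:
            return False
        if kind in ("int", "float") and spec[1] != spec[2]:
            return False
    return True


def sample_random(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "categorical":
            params[name] = spec[1][rng.integers(len(spec[1]))]
        elif kind == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "float":
            params[name] = float(rng.uniform(spec[1], spec[2]))
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
    return params


def _parzen(obs: np.ndarray, lo: float, hi: float):
    """Gaussian Parzen mixture over [lo, hi] with a wide prior component.

    Each observation becomes a kernel whose bandwidth is the larger of its
    gaps to the neighbouring observations (isolated good points keep wide
    kernels, clusters sharpen), clipped to [span/20, span].
    """
    span = hi - lo
    if span == 0:
        return np.array([lo]), np.array([1.0])
    if obs.size == 0:
        return np.array([0.5 * (lo + hi)]), np.array([span])
    order = np.argsort(obs)
    srt = obs[order]
    padded = np.concatenate([[lo], srt, [hi]])
    gaps = np.maximum(padded[2:] - padded[1:-1], padded[1:-1] - padded[:-2])
    bw_sorted = np.clip(gaps, span / 20.0, span)
    bws = np.empty_like(bw_sorted)
    bws[order] = bw_sorted
    centers = np.concatenate([obs, [0.5 * (lo + hi)]])
    bws = np.concatenate([bws, [span]])
    return centers, bws


def _parzen_logpdf(x: float, centers: np.ndarray, bws: np.ndarray) -> float:
    z = (x - centers) / bws
    dens = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * bws)
    return float(np.log(dens.mean() + 1e-300))


def _cat_probs(obs, choices) -> np.ndarray:
    counts = np.array([sum(1 for o in obs if o == c) for c in choices], dtype=float)
    counts += 1.0  # Dirichlet smoothing
    return counts / counts.sum()


def _suggest(
    space: dict,
    trials: list[tuple[dict, float]],
    rng: np.random.Generator,
    gamma: float,
    n_candidates: int,
) -> dict:
    scores = np.array([s for _, s in trials])
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good_idx = set(np.argsort(-scores, kind="stable")[:n_good].tolist())
    good = [trials[i][0] for i in range(len(trials)) if i in good_idx]
    bad = [trials[i][0] for i in range(len(trials)) if i not in good_idx]

    models = {}
    for name, spec in space.items():
        kind = spec[0]
        g_obs = [t[name] for t in good]
        b_obs = [t[name] for t in bad]
        if kind == "categorical":
            models[name] = (
                _cat_probs(g_obs, spec[1]),
                _cat_probs(b_obs, spec[1]),
            )
        else:
            lo, hi = float(spec[1]), float(spec[2])
            models[name] = (
                _parzen(np.asarray(g_obs, dtype=float), lo, hi),
                _parzen(np.asarray(b_obs, dtype=float), lo, hi),
            )

    best_cand, best_ratio = None, -np.inf
    for _ in range(n_candidates):
        cand, ratio = {}, 0.0
        for name, spec in space.items():
            kind = spec[0]
            good_m, bad_m = models[name]
            if kind == "categorical":
                choices = spec[1]
                j = rng.choice(len(choices), p=good_m)
                cand[name] = choices[j]
                ratio += np.log(good_m[j]) - np.log(bad_m[j])
            else:
                lo, hi = float(spec[1]), float(spec[2])
                centers, bws = good_m
                j = rng.integers(centers.size)
                x = float(np.clip(rng.normal(centers[j], bws[j]), lo, hi))
                if kind == "int":
                    x = int(round(x))
                cand[name] = x
                ratio += _parzen_logpdf(float(x), *good_m) - _parzen_logpdf(
                    float(x), *bad_m
                )
        if ratio > best_ratio:
            best_cand, best_ratio = cand, ratio
    return best_cand


def tpe_optimize(
    objective,
    space: dict,
    n_evaluations: int,
    seed: int = 0,
    n_startup: int = 10,
    gamma: float = 0.15,
    n_candidates: int = 24,
) -> TpeResult:
    """Maximise ``objective(params)`` over ``space`` with ``n_evaluations`` calls.

    The first ``n_startup`` parameter sets are drawn uniformly at random;
    subsequent sets come from the Parzen density-ratio rule. Identical
    seed, space and objective give an identical trial sequence.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    if _is_singleton(space):
        n_evaluations = 1
    trials: list[tuple[dict, float]] = []
    for i in range(n_evaluations):
        if i < n_startup or len(trials) < 2:
            params = sample_random(space, rng)
        else:
            params = _suggest(space, trials, rng, gamma, n_candidates)
        trials.append((params, float(objective(params))))
    best_i = int(np.argmax([s for _, s in trials]))
    log = pd.DataFrame([{**p, "score": s} for p, s in trials])
    return TpeResult(
        best_params=dict(trials[best_i][0]),
        best_score=trials[best_i][1],
        trials=log,
    )
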