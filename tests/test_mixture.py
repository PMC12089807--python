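"""EM mixture fitting, model selection, severity ordering, trajectory labels."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

import chftraj.mixture as mixture_mod
from chftraj.mixture import (
    ClusterSolution,
    DegeneracyError,
    MixtureFit,
    binarize_severity,
    derive_trajectory_labels,
    fit_univariate_gmm,
    information_criteria,
    order_by_severity,
    select_k,
)


def _two_component_sample(seed, n=1000, means=(5.0, 30.0), sd=2.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    return np.concatenate(
        [rng.normal(means[0], sd, half), rng.normal(means[1], sd, n - half)]
    )


def test_k1_closed_form_mle():
    x = np.array([1.0, 2.0, 3.0, 7.0, 11.0])
    fit = fit_univariate_gmm(x, k=1)
    assert fit.means[0] == pytest.approx(x.mean(), abs=1e-12)
    assert fit.variances[0] == pytest.approx(np.var(x), abs=1e-12)  # biased MLE
    assert fit.weights[0] == 1.0 and fit.converged


def test_two_component_parameter_recovery():
    """Recovered means within 0.5 and weights within 0.05 of the generator."""
    for seed in range(20):
        x = _two_component_sample(seed)
        fit = fit_univariate_gmm(x, k=2, seed=seed)
        means = np.sort(fit.means)
        assert abs(means[0] - 5.0) < 0.5 and abs(means[1] - 30.0) < 0.5
        w = fit.weights[np.argsort(fit.means)]
        assert abs(w[0] - 0.5) < 0.05


def test_em_log_likelihood_ascends():
    for seed in range(5):
        x = _two_component_sample(seed, n=400)
        for k in (2, 3, 4):
            fit = fit_univariate_gmm(x, k=k, seed=seed)
            diffs = np.diff(fit.ll_trace)
            assert np.all(diffs >= -1e-7), f"descent at k={k}, seed={seed}"


def test_responsibilities_are_a_proper_posterior():
    x = _two_component_sample(3, n=500)
    fit = fit_univariate_gmm(x, k=3, seed=3)
    assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)
    assert abs(fit.weights.sum() - 1.0) < 1e-10
    assert np.array_equal(
        fit.hard_assignments(), np.argmax(fit.responsibilities, axis=1)
    )


def test_matches_sklearn_gaussian_mixture():
    """Independent EM implementation reaches the same optimum."""
    x = _two_component_sample(0, n=800)
    ours = fit_univariate_gmm(x, k=2, seed=0)
    theirs = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(
        x.reshape(-1, 1)
    )
    assert np.allclose(np.sort(ours.means), np.sort(theirs.means_.ravel()), atol=0.1)
    ll_theirs = theirs.score(x.reshape(-1, 1)) * x.size
    assert ours.log_likelihood == pytest.approx(ll_theirs, rel=1e-3)


def test_degenerate_inputs_rejected():
    with pytest.raises(DegeneracyError, match="distinct"):
        fit_univariate_gmm(np.array([1.0, 1.0, 2.0, 2.0]), k=3)
    with pytest.raises(ValueError, match="finite"):
        fit_univariate_gmm(np.array([1.0, np.nan]), k=1)
    with pytest.raises(DegeneracyError, match="distinct"):
        fit_univariate_gmm(np.full(10, 3.0), k=2)


def test_information_criteria_formulas():
    def fake(k, ll):
        return MixtureFit(k, np.ones(k) / k, np.zeros(k), np.ones(k), ll,
                          np.zeros((1, k)), 1, True, np.array([ll]))

    aic, bic = information_criteria(fake(1, -100.0), n=100)
    assert aic == pytest.approx(204.0)
    assert bic == pytest.approx(2 * np.log(100) + 200)
    aic, bic = information_criteria(fake(2, 0.0), n=1)
    assert aic == pytest.approx(10.0) and bic == pytest.approx(0.0)
    rng = np.random.default_rng(0)
    fit = fit_univariate_gmm(rng.normal(size=50), k=2, seed=0)
    aic, bic = information_criteria(fit, 50)
    p = 3 * 2 - 1
    assert aic == pytest.approx(2 * p - 2 * fit.log_likelihood, abs=1e-12)
    assert bic == pytest.approx(p * np.log(50) - 2 * fit.log_likelihood, abs=1e-12)


def test_select_k_recovers_generative_k_small():
    hits = 0
    for seed in range(10):
        x = np.round(_two_component_sample(seed, n=783))
        hits += select_k(x, seed=seed, n_restarts=3).k_selected == 2
    assert hits >= 9


def test_select_k_tie_breaks_to_smallest_k(monkeypatch):
    """With silhouette forced constant, parsimony picks the smallest k."""
    monkeypatch.setattr(mixture_mod, "silhouette_score", lambda *a: 0.5)
    x = _two_component_sample(0, n=200)
    sol = select_k(x, k_range=range(2, 6), seed=0, n_restarts=2)
    assert sol.k_selected == 2
    assert (sol.diagnostics.silhouette == 0.5).all()


def test_select_k_reports_all_failures():
    with pytest.raises(DegeneracyError, match="k=3"):
        select_k(np.array([0.0, 0.0, 1.0, 1.0]), k_range=range(3, 5))


def test_order_by_severity():
    def fake(means, variances):
        k = len(means)
        return MixtureFit(k, np.ones(k) / k, np.array(means, float),
                          np.array(variances, float), 0.0, np.zeros((1, k)),
                          1, True, np.zeros(1))

    assert order_by_severity(fake([24, 9], [1, 1])).tolist() == [1, 0]
    assert order_by_severity(fake([9, 24, 40], [1, 1, 1])).tolist() == [0, 1, 2]
    # equal means: lower variance ranks first
    assert order_by_severity(fake([10, 10], [4, 1])).tolist() == [1, 0]


def _solution(assignments, severity_order, k):
    fit = MixtureFit(k, np.ones(k) / k, np.arange(k, dtype=float), np.ones(k),
                     0.0, np.zeros((len(assignments), k)), 1, True, np.zeros(1))
    import pandas as pd

    return ClusterSolution(k, np.asarray(assignments), 0.5, fit,
                           pd.DataFrame(), np.asarray(severity_order))


def test_binarize_merges_all_non_minimal_clusters():
    # baseline k=2: rank-0 component -> low
    sol = _solution([0, 1, 0], severity_order=[0, 1], k=2)
    assert binarize_severity(sol).tolist() == ["low", "high", "low"]
    # follow-up k=3: moderate (rank 1) and severe (rank 2) both -> high
    sol = _solution([0, 1, 2], severity_order=[0, 1, 2], k=3)
    assert binarize_severity(sol).tolist() == ["low", "high", "high"]


def test_trajectory_label_rule():
    base = np.array(["low", "high", "low", "high"])
    fup = np.array(["low", "low", "high", "high"])
    labels = derive_trajectory_labels(base, fup)
    assert labels.tolist() == [
        "good_prognosis",
        "remitting_course",
        "clinical_worsening",
        "persistent_course",
    ]
    with pytest.raises(ValueError, match="length"):
        derive_trajectory_labels(base, fup[:3])
    with pytest.raises(ValueError, match="low"):
        derive_trajectory_labels(np.array(["LOW"]), np.array(["low"]))
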