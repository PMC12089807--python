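"""One-vs-rest targets, metrics, nested CV leakage and performance."""

import numpy as np
import pytest

from chftraj import (
    CVPlan,
    HyperparameterSpace,
    compute_metrics,
    fit_final_model,
    make_binary_targets,
    nested_cv_evaluate,
    tune_hyperparameters,
)
from chftraj.classifier import decode_params, default_param_space
from chftraj.cohort import TRAJECTORY_CLASSES

SMALL_SPACE = HyperparameterSpace(n_trees=20, n_evaluations=6)
SMALL_PLAN = CVPlan(outer_folds=4, outer_repeats=1, inner_folds=3, seed=0)


def _planted(seed, n=240, informative=0.0):
    """Binary problem with one informative feature among noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8))
    y = (rng.random(n) < 0.25).astype(int)
    X[:, 0] += informative * y
    return X, y


def test_binary_targets_partition_the_cohort():
    labels = np.array(TRAJECTORY_CLASSES, dtype=object)
    targets = make_binary_targets(labels)
    assert targets["good_prognosis"].tolist() == [1, 0, 0, 0]
    stacked = np.stack(list(targets.values()))
    assert (stacked.sum(axis=0) == 1).all()


def test_binary_targets_degenerate_and_counts():
    one_class = np.repeat("good_prognosis", 5)
    targets = make_binary_targets(one_class)
    assert targets["good_prognosis"].sum() == 5
    assert all(targets[c].sum() == 0 for c in TRAJECTORY_CLASSES[1:])

    counts = (155, 174, 85, 369)
    labels = np.repeat(np.array(TRAJECTORY_CLASSES, dtype=object), counts)
    targets = make_binary_targets(labels)
    assert [targets[c].sum() for c in TRAJECTORY_CLASSES] == list(counts)

    with pytest.raises(ValueError, match="unknown"):
        make_binary_targets(np.array(["mystery_class"]))


def test_metrics_identity_prediction():
    y = np.array([0, 1, 1, 0, 1])
    m = compute_metrics(y, y, y.astype(float))
    assert m["f1"] == 1.0 and m["accuracy"] == 1.0
    assert np.allclose(m["normalised_confusion"], np.eye(2))


def test_metrics_hand_computed_cells():
    # TP=2, FP=1, FN=1, TN=6 -> P = R = 2/3, F1 = 2/3, accuracy = 0.8
    y_true = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    y_pred = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0])
    m = compute_metrics(y_true, y_pred)
    assert m["f1"] == pytest.approx(2 / 3)
    assert m["accuracy"] == pytest.approx(0.8)
    assert np.allclose(m["normalised_confusion"].sum(axis=1), 1.0, atol=1e-10)
    assert m["normalised_confusion"][1, 1] == pytest.approx(2 / 3)


def test_metrics_constant_score_and_single_class():
    y = np.array([0, 1, 0, 1])
    m = compute_metrics(y, y, np.full(4, 0.5))
    assert m["auroc"] == pytest.approx(0.5)
    m = compute_metrics(np.ones(4, int), np.ones(4, int), np.full(4, 0.7))
    assert np.isnan(m["auroc"]) and np.isnan(m["auprc"])  # flagged, not 0
    # zero precision+recall -> F1 defined as 0
    assert compute_metrics(np.array([1, 0]), np.array([0, 1]))["f1"] == 0.0


def test_tuning_requires_both_classes_and_is_deterministic():
    X, y = _planted(0, informative=2.0)
    with pytest.raises(ValueError, match="single class"):
        tune_hyperparameters(X, np.zeros_like(y), SMALL_SPACE)
    a = tune_hyperparameters(X, y, SMALL_SPACE, seed=3)
    b = tune_hyperparameters(X, y, SMALL_SPACE, seed=3)
    assert a.trials.equals(b.trials) and a.best_params == b.best_params


def test_singleton_space_tunes_in_one_evaluation():
    X, y = _planted(1, informative=2.0)
    space = HyperparameterSpace(
        n_trees=10,
        n_evaluations=50,
        params={"min_samples_leaf": ("int", 2, 2),
                "criterion": ("categorical", ("gini",))},
    )
    res = tune_hyperparameters(X, y, space, inner_folds=3)
    assert len(res.trials) == 1
    assert res.best_params == {"min_samples_leaf": 2, "criterion": "gini"}


def test_decode_params_covers_all_modes():
    raw = {
        "criterion": "entropy",
        "class_weight": "none",
        "max_depth_mode": "limited",
        "max_depth": 7,
        "max_features_mode": "fraction",
        "max_features_frac": 0.4,
        "min_samples_leaf": 3,
        "min_samples_split": 9,
    }
    decoded = decode_params(raw)
    assert decoded == {
        "criterion": "entropy",
        "class_weight": None,
        "max_depth": 7,
        "max_features": 0.4,
        "min_samples_leaf": 3,
        "min_samples_split": 9,
    }
    assert decode_params({"max_depth_mode": "unlimited", "max_depth": 5}) == {
        "max_depth": None
    }


def test_nested_cv_separable_data_scores_high():
    X, y = _planted(2, informative=6.0)
    report = nested_cv_evaluate(X, y, SMALL_PLAN, SMALL_SPACE)
    assert report.summary["f1"][0] >= 0.95


def test_nested_cv_fold_hygiene(small_cohort, small_cohort_X):
    """No outer-test row is available during tuning; folds stay stratified."""
    y = make_binary_targets(small_cohort.true_class.to_numpy())["persistent_course"]
    report = nested_cv_evaluate(small_cohort_X, y, SMALL_PLAN, SMALL_SPACE)
    global_rate = y.mean()
    for tr, te in report.fold_indices:
        assert np.intersect1d(tr, te).size == 0
        assert set(tr) | set(te) == set(range(len(y)))
        assert abs(y[te].mean() - global_rate) <= 0.05 + 1e-9
    per_fold = report.per_fold
    for metric in ("f1", "accuracy", "auprc", "auroc"):
        vals = per_fold[metric].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()
    assert np.allclose(report.confusion_mean.sum(axis=1), 1.0, atol=1e-10)


def test_tuned_never_worse_than_defaults_on_imbalanced_cohort(
    small_cohort, small_cohort_X
):
    """F1-directed tuning should not lose to default settings (paired seeds)."""
    y = make_binary_targets(small_cohort.true_class.to_numpy())["remitting_course"]
    from chftraj.inference import _cv_f1

    diffs = []
    for seed in range(3):
        plan = CVPlan(outer_folds=4, outer_repeats=1, inner_folds=3, seed=seed)
        tuned = nested_cv_evaluate(small_cohort_X, y, plan, SMALL_SPACE)
        default_f1 = _cv_f1(small_cohort_X, y, {}, plan, n_trees=20, seed=seed)
        diffs.append(tuned.summary["f1"][0] - default_f1)
    assert np.mean(diffs) >= 0


def test_final_model_deterministic_and_500_trees_default():
    X, y = _planted(3, n=120, informative=5.0)
    a = fit_final_model(X, y, {}, n_trees=40, seed=1)
    b = fit_final_model(X, y, {}, n_trees=40, seed=1)
    assert np.array_equal(a.predict_proba(X), b.predict_proba(X))
    assert [t.tree_.node_count for t in a.estimators_] == [
        t.tree_.node_count for t in b.estimators_
    ]
    from chftraj.classifier import compute_metrics as cm

    assert cm(y, a.predict(X))["f1"] >= 0.9
    assert fit_final_model(X, y, {}).n_estimators == 500
    with pytest.raises(ValueError, match="single class"):
        fit_final_model(X, np.zeros_like(y), {})


def test_default_space_has_fixed_trees_and_paper_ranges():
    space = HyperparameterSpace()
    assert space.n_trees == 500 and space.n_evaluations == 500
    params = default_param_space()
    assert params["criterion"][1] == ("gini", "entropy")
    assert params["min_samples_leaf"] == ("int", 1, 20)
    assert params["min_samples_split"] == ("int", 2, 20)
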