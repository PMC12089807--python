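"""Permutation p-values, BH-FDR, and null-generation contracts."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from chftraj import CVPlan, bh_fdr, make_binary_targets, one_sided_p
from chftraj.cohort import TRAJECTORY_CLASSES, default_config, generate_cohort
from chftraj.cohort import feature_columns
from chftraj.inference import (
    NullSet,
    build_null,
    params_checksum,
    permuted_run,
    run_inference,
)

FROZEN = {c: {"min_samples_leaf": 2} for c in TRAJECTORY_CLASSES}
TINY_PLAN = CVPlan(outer_folds=2, outer_repeats=1, inner_folds=2, seed=0)


def bh_stepup_oracle(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_one_sided_p_conventions():
    null = np.arange(1000) / 1000.0
    assert one_sided_p(2.0, null) == pytest.approx(1 / 1001)
    assert one_sided_p(-1.0, null) == 1.0
    null = np.arange(201, dtype=float)  # odd length, median 100
    # exceedances: values >= 100 -> 101 of them
    assert one_sided_p(100.0, null) == pytest.approx(102 / 202)
    with pytest.raises(ValueError, match="empty"):
        one_sided_p(1.0, np.array([]))


def test_one_sided_p_is_super_uniform_under_the_null():
    """P(p <= t) <= t + 1/(B+1) when the statistic is exchangeable with its null."""
    rng = np.random.default_rng(0)
    B = 199
    pvals = []
    for _ in range(50):
        draws = rng.normal(size=B + 1)
        pvals.append(one_sided_p(draws[0], draws[1:]))
    pvals = np.array(pvals)
    for t in np.linspace(0.05, 0.95, 19):
        assert np.mean(pvals <= t) <= t + 1 / (B + 1) + 0.12  # MC slack at 50 reps


def test_bh_fdr_worked_examples():
    assert bh_fdr([0.03]) == pytest.approx([0.03])
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        bh_fdr([0.5, 1.2])


@seed(7)
@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_fdr_equals_stepup_oracle_and_is_monotone(p):
    q = bh_fdr(p)
    assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


def _tiny_cohort(seed=0, n=120):
    return generate_cohort(default_config(n_participants=n, seed=seed))


def test_permuted_run_preserves_counts_and_is_seeded():
    co = _tiny_cohort()
    X = co[feature_columns(co)].to_numpy(float)
    labels = co.true_class.to_numpy()
    f1_a, imp_a, ck = permuted_run(X, labels, FROZEN, TINY_PLAN, seed=9, n_trees=5)
    f1_b, imp_b, _ = permuted_run(X, labels, FROZEN, TINY_PLAN, seed=9, n_trees=5)
    assert f1_a == f1_b
    for c in TRAJECTORY_CLASSES:
        assert np.array_equal(imp_a[c], imp_b[c])
    assert ck == params_checksum(FROZEN)
    with pytest.raises(ValueError, match="frozen"):
        permuted_run(X, labels, {}, TINY_PLAN, seed=0)
    with pytest.raises(ValueError, match="missing classes"):
        permuted_run(X, labels, {"good_prognosis": {}}, TINY_PLAN, seed=0)


def test_permutation_preserves_class_counts():
    co = _tiny_cohort()
    labels = co.true_class.to_numpy()
    rng = np.random.default_rng(4)
    shuffled = labels[rng.permutation(labels.size)]
    for c in TRAJECTORY_CLASSES:
        assert np.sum(shuffled == c) == np.sum(labels == c)


def test_build_null_has_frozen_checksums():
    co = _tiny_cohort()
    X = co[feature_columns(co)].to_numpy(float)
    nulls = build_null(X, co.true_class.to_numpy(), FROZEN, TINY_PLAN,
                       B=4, seed=0, n_trees=5)
    assert nulls.frozen()
    assert len(nulls.params_checksums) == 4
    for c in TRAJECTORY_CLASSES:
        assert nulls.f1[c].shape == (4,)
        assert nulls.importance[c].shape == (4, X.shape[1])


def _fake_nulls(B=50, p=3, seed=0):
    rng = np.random.default_rng(seed)
    return NullSet(
        f1={c: rng.uniform(0, 0.4, B) for c in TRAJECTORY_CLASSES},
        importance={c: rng.dirichlet(np.ones(p), B) for c in TRAJECTORY_CLASSES},
        B=B,
        seed=seed,
        params_checksums=["same"] * B,
    )


def test_run_inference_families_corrected_independently():
    feature_names = ["a", "b", "c"]
    nulls = _fake_nulls()
    real_imp = {c: np.full(3, 1 / 3) for c in TRAJECTORY_CLASSES}
    weak = {c: 0.2 for c in TRAJECTORY_CLASSES}
    strong = dict(weak, good_prognosis=0.99)  # extreme performance p in family 1
    perf_w, imp_w = run_inference(weak, real_imp, nulls, feature_names)
    perf_s, imp_s = run_inference(strong, real_imp, nulls, feature_names)
    assert not imp_w.table.drop(columns=[]).equals(perf_w.table)
    assert imp_w.table.q.tolist() == imp_s.table.q.tolist()
    assert perf_w.table.q.tolist() != perf_s.table.q.tolist()
    assert len(perf_w.table) == 4 and len(imp_w.table) == 12
    assert (perf_w.table.significant == (perf_w.table.q <= 0.05)).all()


def test_run_inference_validates_family_shapes():
    nulls = _fake_nulls()
    real_imp = {c: np.full(3, 1 / 3) for c in TRAJECTORY_CLASSES}
    real_f1 = {c: 0.5 for c in TRAJECTORY_CLASSES}
    with pytest.raises(ValueError, match="expected 4"):
        run_inference(real_f1, real_imp, nulls, ["a", "b", "c", "d"])
    with pytest.raises(ValueError, match="classes"):
        run_inference({"good_prognosis": 0.5}, real_imp, nulls, ["a", "b", "c"])
    thawed = _fake_nulls()
    thawed.params_checksums[0] = "different"
    with pytest.raises(ValueError, match="frozen"):
        run_inference(real_f1, real_imp, thawed, ["a", "b", "c"])


def test_null_f1_draws_match_exchangeable_real_f1():
    """On a no-signal cohort, permuted and real F1 come from one distribution."""
    from scipy.stats import ks_2samp

    from chftraj.inference import _cv_f1

    cfg = default_config(n_participants=150, effect_sizes={})
    co = generate_cohort(cfg)
    X = co[feature_columns(co)].to_numpy(float)
    labels = co.true_class.to_numpy()
    y = make_binary_targets(labels)["persistent_course"]
    params = FROZEN["persistent_course"]
    rng = np.random.default_rng(0)
    real = [
        _cv_f1(X, y, params, CVPlan(2, 1, 2, seed=s), n_trees=8, seed=s)
        for s in range(60)
    ]
    null = []
    for s in range(60):
        perm = rng.permutation(y.size)
        null.append(
            _cv_f1(X, y[perm], params, CVPlan(2, 1, 2, seed=s), n_trees=8, seed=s)
        )
    assert ks_2samp(real, null).pvalue > 0.01
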