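"""End-to-end orchestration: simulate/ingest -> cluster -> classify -> explain -> test.

The pipeline reproduces the full analysis chain on a cohort table:
univariate mixture clustering of the two score columns, low/high
binarisation and trajectory labelling, one-vs-rest nested-CV random
forests, importance/SHAP attribution, and permutation-null inference
with BH-FDR. Every stochastic stage takes an explicit seed, all
artifacts are written as delimited text under the output directory, and
a machine-readable manifest (config hash, package version, seeds) makes
reruns comparable: the same config and seeds give the same manifest
hash.

Two execution profiles are provided. ``full`` uses the complete
protocol budgets (500 TPE evaluations, B = 1000 permutations, 10x5
outer CV, 500-tree forests), which is hours-scale on one CPU; ``ci``
is a documented scaled-down profile for quick runs. The profile in
force is declared in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from chftraj.classifier import (
    CVPlan,
    HyperparameterSpace,
    fit_final_model,
    make_binary_targets,
    nested_cv_evaluate,
    tune_hyperparameters,
)
from chftraj.cohort import (
    TRAJECTORY_CLASSES,
    CohortConfig,
    export_ground_truth,
    feature_columns,
    generate_cohort,
)
from chftraj.explain import direction_summary, impurity_importance, shap_attributions
from chftraj.inference import build_null, run_inference
from chftraj.mixture import binarize_severity, derive_trajectory_labels, select_k

logger = logging.getLogger(__name__)

_pkg_version = "0.1.0"

__all__ = [
    "PROFILES",
    "RunConfig",
    "ResultsBundle",
    "TrajectorySummary",
    "ingest_cohort",
    "summarize_trajectories",
    "run_pipeline",
]

#: budget presets; "full" is the complete protocol, "ci" a scaled-down run
PROFILES = {
    "full": {"n_evaluations": 500, "B": 1000, "outer_repeats": 5, "n_trees": 500},
    "ci": {"n_evaluations": 20, "B": 200, "outer_repeats": 1, "n_trees": 100},
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with per-stage seeds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_path: str | None = None  # when set, ingest instead of simulate
    feature_names: list | None = None  # default: every non-reserved column
    k_range: tuple = (2, 12)
    cv: CVPlan = field(default_factory=CVPlan)
    space: HyperparameterSpace = field(default_factory=HyperparameterSpace)
    B: int = 1000
    alpha: float = 0.05
    profile: str = "full"
    out_dir: str = "results/run"
    seeds: dict = field(
        default_factory=lambda: {
            "cohort": 0,
            "clustering": 1,
            "cv": 2,
            "tuning": 3,
            "permutation": 4,
        }
    )

    def resolved(self) -> "RunConfig":
        """Apply the profile's budget caps to CV plan, space and B."""
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        return replace(
            self,
            cv=replace(self.cv, outer_repeats=min(self.cv.outer_repeats,
                                                  prof["outer_repeats"]),
                       seed=self.seeds["cv"]),
            space=self.space.scaled(
                n_trees=min(self.space.n_trees, prof["n_trees"]),
                n_evaluations=min(self.space.n_evaluations, prof["n_evaluations"]),
            ),
            B=min(self.B, prof["B"]),
        )

    def validate_features(self, cohort: pd.DataFrame) -> list:
        names = self.feature_names or feature_columns(cohort)
        leaky = {"bdi_baseline", "bdi_followup", "true_class"} & set(names)
        if leaky:
            raise ValueError(
                f"severity scores/labels listed as classifier features: "
                f"{sorted(leaky)} — baseline severity is excluded to prevent "
                "data leakage (clustering was based on it)"
            )
        missing = set(names) - set(cohort.columns)
        if missing:
            raise ValueError(f"feature columns absent from cohort: {sorted(missing)}")
        return list(names)


@dataclass
class TrajectorySummary:
    table: pd.DataFrame  # class, n, pct
    n: int
    baseline_low_pct: float | None  # good_prognosis + clinical_worsening
    followup_low_pct: float | None  # good_prognosis + remitting_course


def summarize_trajectories(labels) -> TrajectorySummary:
    """Counts and cohort percentages per trajectory class (2 dp reporting).

    Also derives the timepoint cluster percentages implied by the label
    rule: baseline-low = good prognosis + clinical worsening;
    follow-up-low = good prognosis + remitting course.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n == 0:
        return TrajectorySummary(
            pd.DataFrame(columns=["class", "n", "pct"]), 0, None, None
        )
    counts = {c: int(np.sum(labels == c)) for c in TRAJECTORY_CLASSES}
    table = pd.DataFrame(
        {
            "class": list(TRAJECTORY_CLASSES),
            "n": [counts[c] for c in TRAJECTORY_CLASSES],
            "pct": [round(100.0 * counts[c] / n, 2) for c in TRAJECTORY_CLASSES],
        }
    )
    baseline_low = counts["good_prognosis"] + counts["clinical_worsening"]
    followup_low = counts["good_prognosis"] + counts["remitting_course"]
    return TrajectorySummary(
        table=table,
        n=n,
        baseline_low_pct=round(100.0 * baseline_low / n, 2),
        followup_low_pct=round(100.0 * followup_low / n, 2),
    )


def ingest_cohort(path: str | Path, score_range=(0.0, 63.0)) -> pd.DataFrame:
    """Read and validate a cohort table (complete-case).

    Rows with any missing value are dropped with a logged count; scores
    outside the 0-63 severity scale are a hard error.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "bdi_baseline", "bdi_followup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks required columns: {sorted(missing)}")
    before = len(df)
    df = df.dropna().reset_index(drop=True)
    dropped = before - len(df)
    if dropped:
        logger.warning("dropped %d incomplete rows (complete-case analysis)", dropped)
    lo, hi = score_range
    for col in ("bdi_baseline", "bdi_followup"):
        bad = df[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} rows have {col} outside [{lo}, {hi}] "
                f"(first offending value: {bad[col].iloc[0]})"
            )
    return df


@dataclass
class ResultsBundle:
    cohort: pd.DataFrame
    feature_names: list
    baseline_solution: object
    followup_solution: object
    labels: np.ndarray
    trajectory_summary: TrajectorySummary
    performance: dict        # class -> PerformanceReport
    final_params: dict       # class -> tuned raw params
    importance: dict         # class -> ImportanceVector
    shap: dict               # class -> ShapMatrix
    directions: dict         # class -> DirectionSummary
    inference_performance: object
    inference_importance: object
    manifest: dict
    out_dir: Path


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, dict):
            return {str(k): v for k, v in o.items()}
        return str(o)

    payload = json.dumps(
        {
            "cohort": {str(k): default(v) for k, v in asdict(config.cohort).items()},
            "input_path": config.input_path,
            "k_range": list(config.k_range),
            "cv": asdict(config.cv),
            "space": {
                "n_trees": config.space.n_trees,
                "n_evaluations": config.space.n_evaluations,
                "params": {k: str(v) for k, v in config.space.params.items()},
            },
            "B": config.B,
            "alpha": config.alpha,
            "profile": config.profile,
            "seeds": config.seeds,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the full analysis and write all artifacts under ``out_dir``."""
    config = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    t0 = _stage("cohort")
    if config.input_path is not None:
        cohort = ingest_cohort(config.input_path)
    else:
        cohort = generate_cohort(
            replace(config.cohort, seed=config.seeds["cohort"])
        )
        export_ground_truth(cohort, out / "ground_truth.csv",
                            config.cohort.effect_sizes)
    feats = config.validate_features(cohort)
    cohort.to_csv(out / "cohort.csv", index=False)

    # --- clustering and trajectory labels ---------------------------------
    _stage("clustering")
    lo, hi = config.k_range
    k_range = range(lo, hi + 1)
    try:
        base_sol = select_k(cohort["bdi_baseline"].to_numpy(), k_range,
                            seed=config.seeds["clustering"])
        fup_sol = select_k(cohort["bdi_followup"].to_numpy(), k_range,
                           seed=config.seeds["clustering"])
    except Exception as exc:
        raise RuntimeError(f"stage 'clustering' failed: {exc}") from exc
    base_sol.diagnostics.to_csv(out / "cluster_diagnostics_baseline.csv", index=False)
    fup_sol.diagnostics.to_csv(out / "cluster_diagnostics_followup.csv", index=False)

    labels = derive_trajectory_labels(
        binarize_severity(base_sol), binarize_severity(fup_sol)
    )
    label_table = pd.DataFrame(
        {"participant_id": cohort["participant_id"], "trajectory": labels}
    )
    label_table.to_csv(out / "trajectory_labels.csv", index=False)
    summary = summarize_trajectories(labels)
    summary.table.to_csv(out / "trajectory_summary.csv", index=False)

    # --- one-vs-rest classification ---------------------------------------
    _stage("classification")
    X = cohort[feats].to_numpy(dtype=float)
    targets = make_binary_targets(labels)
    performance, final_params = {}, {}
    rows = []
    for cls in TRAJECTORY_CLASSES:
        y = targets[cls]
        try:
            report = nested_cv_evaluate(X, y, config.cv, config.space)
            tuned = tune_hyperparameters(
                X, y, config.space, inner_folds=config.cv.inner_folds,
                seed=config.seeds["tuning"],
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'classification' ({cls}) failed: {exc}") from exc
        performance[cls] = report
        final_params[cls] = tuned.best_params
        report.per_fold.assign(**{"class": cls}).to_csv(
            out / f"cv_metrics_{cls}.csv", index=False
        )
        mean, sd = report.summary["f1"]
        rows.append({"class": cls, "f1_mean": mean, "f1_sd": sd,
                     **{f"{m}_mean": report.summary[m][0]
                        for m in ("accuracy", "auprc", "auroc")}})
    pd.DataFrame(rows).to_csv(out / "performance_summary.csv", index=False)

    # --- attribution --------------------------------------------------------
    _stage("explainability")
    importance, shap_by_class, directions = {}, {}, {}
    models = {}
    for cls in TRAJECTORY_CLASSES:
        model = fit_final_model(X, targets[cls], final_params[cls],
                                n_trees=config.space.n_trees,
                                seed=config.seeds["tuning"])
        models[cls] = model
        imp = impurity_importance(model, feats)
        sm = shap_attributions(model, cohort[feats], class_label=cls)
        sm.check_additivity(model, X)
        importance[cls] = imp
        shap_by_class[cls] = sm
        directions[cls] = direction_summary(sm, X)
        long = pd.DataFrame(sm.values, columns=feats)
        long.insert(0, "participant_id", cohort["participant_id"])
        long.to_csv(out / f"shap_{cls}.csv", index=False)

    # --- permutation inference ----------------------------------------------
    _stage("inference")
    nulls = build_null(
        X, labels, final_params, config.cv, B=config.B,
        seed=config.seeds["permutation"], n_trees=config.space.n_trees,
    )
    real_f1 = {c: performance[c].summary["f1"][0] for c in TRAJECTORY_CLASSES}
    real_imp = {c: importance[c].normalised for c in TRAJECTORY_CLASSES}
    perf_res, imp_res = run_inference(real_f1, real_imp, nulls, feats,
                                      alpha=config.alpha)
    perf_res.table.to_csv(out / "inference_performance.csv", index=False)
    sign_map = {
        (cls, row.feature): row.sign
        for cls in TRAJECTORY_CLASSES
        for row in directions[cls].table.itertuples()
    }
    imp_table = imp_res.table.assign(
        sign=[
            sign_map[(cls, feat)]
            for cls, feat in zip(imp_res.table["class"], imp_res.table["feature"])
        ]
    )
    imp_table.to_csv(out / "inference_importance.csv", index=False)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package_version": _pkg_version,
        "config_hash": _config_hash(config),
        "profile": config.profile,
        "seeds": config.seeds,
        "budgets": {
            "n_evaluations": config.space.n_evaluations,
            "n_trees": config.space.n_trees,
            "B": config.B,
            "outer_folds": config.cv.outer_folds,
            "outer_repeats": config.cv.outer_repeats,
            "inner_folds": config.cv.inner_folds,
        },
        "n_participants": int(len(cohort)),
        "label_digest": hashlib.sha256(
            ",".join(labels.astype(str)).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ResultsBundle(
        cohort=cohort,
        feature_names=feats,
        baseline_solution=base_sol,
        followup_solution=fup_sol,
        labels=labels,
        trajectory_summary=summary,
        performance=performance,
        final_params=final_params,
        importance=importance,
        shap=shap_by_class,
        directions=directions,
        inference_performance=perf_res,
        inference_importance=imp_res,
        manifest=manifest,
        out_dir=out,
    )
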