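"""Impurity importance, SHAP attributions and direction calls per class.

Refits each one-vs-rest forest on the full cohort with its tuned
hyperparameters, computes normalised impurity importances and tree-SHAP
attributions over all participants, and summarises each feature's
direction (risk-like vs protective) from the rank correlation between
feature values and attributions.
"""

import json
from pathlib import Path

import pandas as pd

from chftraj import ingest_cohort, make_binary_targets
from chftraj.classifier import fit_final_model
from chftraj.cohort import TRAJECTORY_CLASSES, feature_columns
from chftraj.explain import direction_summary, impurity_importance, shap_attributions

OUT = Path(__file__).resolve().parents[1] / "results"
N_TREES = 100


def main(seed: int = 1) -> None:
    cohort = ingest_cohort(OUT / "cohort.csv")
    labels = pd.read_csv(OUT / "trajectory_labels.csv").trajectory.to_numpy()
    params = json.loads((OUT / "final_params.json").read_text())
    feats = feature_columns(cohort)
    X = cohort[feats].to_numpy(float)
    targets = make_binary_targets(labels)

    tables = []
    for cls in TRAJECTORY_CLASSES:
        model = fit_final_model(X, targets[cls], params[cls],
                                n_trees=N_TREES, seed=seed)
        imp = impurity_importance(model, feats)
        sm = shap_attributions(model, cohort[feats], class_label=cls)
        sm.check_additivity(model, X)
        signs = direction_summary(sm, X).table
        merged = imp.as_frame().merge(signs, on="feature")
        merged.insert(0, "class", cls)
        tables.append(merged)

        shap_long = pd.DataFrame(sm.values, columns=feats)
        shap_long.insert(0, "participant_id", cohort.participant_id)
        shap_long.to_csv(OUT / f"shap_{cls}.csv", index=False)

        top = merged.nlargest(4, "importance")
        print(f"{cls}:")
        for r in top.itertuples():
            print(f"  {r.feature:28s} importance={r.importance:.3f} "
                  f"sign={r.sign}")

    pd.concat(tables).to_csv(OUT / "importance_directions.csv", index=False)
    print(f"wrote {OUT / 'importance_directions.csv'}")


if __name__ == "__main__":
    main()
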