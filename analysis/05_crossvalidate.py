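#!/usr/bin/env python
"""Nested cross-validation of the phase III outcome classifier.

Runs the five-step outer loop (split, stratified univariate selection,
cross-dataset aggregation, incremental feature elimination with inner-CV
model selection, test evaluation) at desk scale: 5 outer folds x 20
repetitions = 100 train-test cycles, inner 5-fold x 3, 2,000 univariate
permutations (full scale was 5 x 200 outer, 5 x 20 inner, 10^4
permutations).  Per-cycle selections and the model-type x feature-count
distribution go to results/; prediction matrices go to scratch/cv.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from targetscreen.crossval import CVConfig, outer_cv
from targetscreen.evaluation import heldout_prediction_frame, unlabeled_prediction_frame
from targetscreen.pipeline import labeled_targets, load_study_dir, prepare_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = load_study_dir(ROOT / "scratch" / "study")
    labeled = labeled_targets(study.labels)
    reduced = [prepare_dataset(ds, labeled) for ds in study.datasets]
    config = CVConfig(
        outer_folds=5,
        outer_reps=20,
        inner_folds=5,
        inner_reps=3,
        n_perm_univariate=2_000,
        min_genes=400,  # scaled-down analogue of the 2,000-gene exclusion
        rf_n_estimators=50,
        seed=1,
    )
    cycles = outer_cv(reduced, study.labels, study.class_map, config)

    cv_dir = ROOT / "scratch" / "cv"
    cv_dir.mkdir(parents=True, exist_ok=True)
    heldout_prediction_frame(cycles).to_csv(cv_dir / "test_predictions.tsv", sep="\t")
    unlabeled_prediction_frame(cycles).to_csv(
        cv_dir / "unlabeled_predictions.tsv", sep="\t"
    )
    pd.DataFrame(
        [
            {
                "rep": c.rep,
                "fold": c.fold,
                "null_model": c.null_model,
                "model_type": None if c.null_model else c.selection.model_type,
                "n_features": 0 if c.null_model else len(c.selection.selected_features),
                "features": ""
                if c.null_model
                else "|".join(c.selection.selected_features),
            }
            for c in cycles
        ]
    ).to_csv(cv_dir / "cycles.tsv", sep="\t", index=False)

    modeled = [c for c in cycles if not c.null_model]
    combo = Counter(
        (c.selection.model_type, len(c.selection.selected_features)) for c in modeled
    )
    combo_table = pd.DataFrame(
        [
            {"model_type": mt, "n_features": k, "cycles": n}
            for (mt, k), n in sorted(combo.items())
        ]
    )
    feat = Counter(f for c in modeled for f in c.selection.selected_features)
    feat_table = pd.DataFrame(
        sorted(feat.items(), key=lambda kv: -kv[1]), columns=["feature", "cycles"]
    )
    results = ROOT / "results"
    combo_table.to_csv(results / "05_model_selection.tsv", sep="\t", index=False)
    feat_table.to_csv(results / "05_feature_selection.tsv", sep="\t", index=False)

    print(f"{len(cycles)} train-test cycles ({len(cycles) - len(modeled)} null)")
    print("\nmodel type x feature count:")
    print(combo_table.to_string(index=False))
    print("\nfeatures by selection count:")
    print(feat_table.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
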