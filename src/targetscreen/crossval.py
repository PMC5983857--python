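"""Nested cross-validation: univariate selection, aggregation, elimination.

Each outer train-test cycle runs five steps with no test-target leakage:

1. split the labeled targets into training and testing folds
   (outcome-stratified);
2. univariate feature selection per dataset on the training targets only,
   using the within-class stratified permutation test with BY adjustment
   (or, in the weak variant, nominal p < 0.05 with no correction);
3. aggregation of the selected features from all datasets into one matrix —
   excluding non-human datasets, small datasets, and fallback-listed
   datasets unless nothing else survived — with min-max scaling fitted on
   the training targets and a cross-dataset cosine redundancy reduction that
   keeps, per group, the feature best correlated with outcome in training;
4. incremental feature elimination guided by random-forest importances,
   with an inner cross-validation loop scoring logistic-regression and
   random-forest candidates; the simplest model within 95% of the maximum
   inner AUROC *and* AUPR wins, preferring logistic regression;
5. refit on the full training set and predict success probabilities for the
   test targets and the unlabeled targets.

With 5 outer folds repeated 200 times this yields exactly 1000 cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dimreduce import ReducedDataset, cosine_matrix
from .outcomes import FAILURE, SUCCESS, UNLABELED
from .permtest import StratifiedNullSpec, _strata_array, build_strata, by_adjust, perm_pvalues

log = logging.getLogger(__name__)

LOGISTIC = "logistic-regression"
FOREST = "random-forest"

STRICT = "strict"
WEAK = "weak"


@dataclass
class CVConfig:
    outer_folds: int = 5
    outer_reps: int = 200
    inner_folds: int = 5
    inner_reps: int = 20
    univariate: str = STRICT  # strict: BY-adjusted < alpha; weak: nominal < alpha
    alpha: float = 0.05
    n_perm_univariate: int = 10_000
    selection_tolerance: float = 0.95
    min_genes: int = 2000
    human_only: bool = True
    fallback_datasets: tuple[str, ...] = ()  # low-coverage; used only as last resort
    r2_threshold: float = 0.5
    rf_n_estimators: int = 100
    lr_c: float = 1.0
    keep_models: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be at least 2")
        if not 0 < self.selection_tolerance <= 1:
            raise ValueError("selection tolerance must lie in (0, 1]")
        if self.univariate not in (STRICT, WEAK):
            raise ValueError(f"unknown univariate mode {self.univariate!r}")


@dataclass
class SelectedFeature:
    dataset: str
    label: str
    p_raw: float
    p_adj: float
    observed_diff: float

    @property
    def qualified_label(self) -> str:
        return f"{self.dataset}::{self.label}"


@dataclass
class AggregatedFeatureMatrix:
    """Min-max scaled feature matrix over all targets with complete data."""

    targets: list[str]
    feature_labels: list[str]  # dataset-qualified labels
    values: np.ndarray  # scaled to [0, 1] on the training targets
    scale_min: np.ndarray
    scale_range: np.ndarray
    n_dropped_targets: int


@dataclass
class ModelSelection:
    model_type: str
    selected_features: list[str]
    inner_scores: list[dict]  # one record per (model_type, k) elimination step


@dataclass
class TrainTestCycle:
    rep: int
    fold: int
    selection: ModelSelection | None
    test_predictions: dict[str, float] = field(default_factory=dict)
    unlabeled_predictions: dict[str, float] = field(default_factory=dict)
    model: object | None = None
    feature_medians: np.ndarray | None = None  # training medians, scaled space

    @property
    def null_model(self) -> bool:
        return self.selection is None


def _make_model(model_type: str, config: CVConfig, seed: int):
    if model_type == LOGISTIC:
        return LogisticRegression(
            class_weight="balanced", C=config.lr_c, max_iter=1000, random_state=seed
        )
    return RandomForestClassifier(
        n_estimators=config.rf_n_estimators,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )


def univariate_select(
    ds: ReducedDataset,
    train_labels: dict[str, str],
    strata: StratifiedNullSpec | None,
    config: CVConfig,
    rng: np.random.Generator,
) -> list[SelectedFeature]:
    """Training-set-only univariate screen of one reduced dataset.

    Strict mode accepts BY-adjusted p < alpha (within this dataset's
    family); weak mode accepts nominal p < alpha with no correction.
    """
    train = [g for g in ds.genes if train_labels.get(g) in (SUCCESS, FAILURE)]
    if not ds.groups or not train:
        return []
    y = np.array([train_labels[g] == SUCCESS for g in train])
    if not y.any() or y.all():
        return []
    X = ds.matrix[ds.gene_index(train)]
    strata_arr = _strata_array(strata, train)
    obs, p, _, _ = perm_pvalues(X, y, config.n_perm_univariate, strata_arr, rng)
    p_adj = by_adjust(p)
    accept = (p_adj < config.alpha) if config.univariate == STRICT else (p < config.alpha)
    return [
        SelectedFeature(ds.source.name, lab, float(pr), float(pa), float(o))
        for lab, pr, pa, o, a in zip(ds.labels, p, p_adj, obs, accept)
        if a
    ]


def _dataset_exclusions(
    selected: dict[str, list[SelectedFeature]],
    datasets: dict[str, ReducedDataset],
    config: CVConfig,
) -> dict[str, list[SelectedFeature]]:
    kept: dict[str, list[SelectedFeature]] = {}
    for name, feats in selected.items():
        if not feats:
            continue
        src = datasets[name].source
        if config.human_only and not src.is_human:
            log.debug("excluding non-human dataset %s", name)
            continue
        if (src.n_genes_total or len(src.genes)) < config.min_genes:
            log.debug("excluding small dataset %s", name)
            continue
        kept[name] = feats
    # fallback-listed datasets only enter when nothing else is available
    primary = {n: f for n, f in kept.items() if n not in config.fallback_datasets}
    return primary if primary else kept


def aggregate_features(
    selected: dict[str, list[SelectedFeature]],
    datasets: dict[str, ReducedDataset],
    train_targets: list[str],
    all_targets: list[str],
    config: CVConfig,
    train_labels: dict[str, str] | None = None,
) -> AggregatedFeatureMatrix | None:
    """Build one min-max-scaled matrix from the per-dataset selections.

    Targets (training, testing or unlabeled) missing any retained feature
    are dropped; scaling parameters come from the training targets only.
    Cross-dataset redundancy is removed by greedy cosine grouping at the
    usual r^2 threshold computed on the training rows; only pairs from
    *different* datasets can group (within one dataset the primary
    reduction already resolved redundancy with the kind-appropriate
    measure).  Each group keeps the feature with the smallest training
    univariate p; ties — frequent
    when several strong features saturate the shared permutation null —
    break toward the larger absolute success-failure difference measured on
    the min-max-scaled values, the only scale on which features from
    different datasets are comparable.
    """
    kept = _dataset_exclusions(selected, datasets, config)
    if not kept:
        return None
    columns, labels, stats = [], [], []
    for name, feats in kept.items():
        ds = datasets[name]
        col_of = {lab: i for i, lab in enumerate(ds.labels)}
        present = {g: i for i, g in enumerate(ds.genes)}
        for f in feats:
            col = np.full(len(all_targets), np.nan)
            rows = [present.get(t) for t in all_targets]
            have = [i for i, r in enumerate(rows) if r is not None]
            col[have] = ds.matrix[[rows[i] for i in have], col_of[f.label]]
            columns.append(col)
            labels.append(f.qualified_label)
            stats.append(f)
    values = np.column_stack(columns)
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.debug("dropping %d target(s) with missing features", n_dropped)
    targets = [t for t, c in zip(all_targets, complete) if c]
    values = values[complete]

    train_set = set(train_targets)
    train_rows = np.array([i for i, t in enumerate(targets) if t in train_set])
    if train_rows.size == 0:
        return None
    lo = values[train_rows].min(axis=0)
    rng_ = values[train_rows].max(axis=0) - lo
    rng_ = np.where(rng_ > 0, rng_, 1.0)
    values = (values - lo) / rng_

    # cross-dataset redundancy reduction on the training rows
    if values.shape[1] > 1:
        if train_labels is not None:
            y_tr = np.array(
                [train_labels.get(targets[i]) == SUCCESS for i in train_rows]
            )
            scaled_diff = np.abs(
                values[train_rows][y_tr].mean(axis=0)
                - values[train_rows][~y_tr].mean(axis=0)
            )
        else:
            scaled_diff = np.array([abs(s.observed_diff) for s in stats])
        sim = cosine_matrix(values[train_rows])
        adjacent = sim**2 >= config.r2_threshold
        np.fill_diagonal(adjacent, False)
        # within-dataset redundancy was already resolved by the primary
        # reduction with the kind-appropriate measure; the aggregate pass
        # only merges the same signal arriving from different datasets
        ds_of = np.array([s.dataset for s in stats])
        adjacent &= ds_of[None, :] != ds_of[:, None]
        order = np.argsort(-adjacent.sum(axis=0), kind="stable")
        assigned = np.zeros(values.shape[1], dtype=bool)
        keep_idx = []
        for seedcol in order:
            if assigned[seedcol]:
                continue
            members = [seedcol] + [
                j for j in np.flatnonzero(adjacent[seedcol]) if not assigned[j]
            ]
            assigned[members] = True
            best = min(members, key=lambda j: (stats[j].p_raw, -scaled_diff[j]))
            keep_idx.append(best)
        keep_idx = sorted(keep_idx)
        values = values[:, keep_idx]
        labels = [labels[j] for j in keep_idx]
        lo, rng_ = lo[keep_idx], rng_[keep_idx]

    return AggregatedFeatureMatrix(
        targets=targets,
        feature_labels=labels,
        values=values,
        scale_min=lo,
        scale_range=rng_,
        n_dropped_targets=n_dropped,
    )


def _inner_cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]] | None:
    """Mean inner-CV AUROC/AUPR per model type, plus RF importances."""
    n_folds = min(config.inner_folds, int(y.sum()), int((~y).sum()))
    if n_folds < 2:
        return None
    scores = {LOGISTIC: [], FOREST: []}
    importances = []
    for _ in range(config.inner_reps):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for tr, te in skf.split(X, y):
            if y[te].all() or not y[te].any():
                continue
            for mt in (LOGISTIC, FOREST):
                model = _make_model(mt, config, int(rng.integers(2**31)))
                model.fit(X[tr], y[tr])
                prob = model.predict_proba(X[te])[:, 1]
                scores[mt].append(
                    (roc_auc_score(y[te], prob), average_precision_score(y[te], prob))
                )
                if mt == FOREST:
                    importances.append(model.feature_importances_)
    out = {}
    for mt, vals in scores.items():
        arr = np.array(vals)
        out[mt] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    out["importances"] = np.mean(importances, axis=0)
    return out


def incremental_elimination(
    matrix: AggregatedFeatureMatrix,
    train_targets: list[str],
    train_labels: dict[str, str],
    config: CVConfig,
    rng: np.random.Generator,
) -> ModelSelection:
    """Backward feature elimination with inner-CV model selection.

    Starting from all features, each step scores both model types by inner
    cross-validation and removes the feature with the lowest mean
    random-forest importance (ties: the later column goes).  Candidates
    within ``selection_tolerance`` of both the maximum AUROC and maximum
    AUPR qualify; the qualifying logistic regression with fewest features is
    chosen, falling back to the qualifying random forest with fewest
    features.
    """
    pos = {t: i for i, t in enumerate(matrix.targets)}
    rows = np.array([pos[t] for t in train_targets if t in pos])
    y = np.array(
        [train_labels[t] == SUCCESS for t in train_targets if t in pos]
    )
    active = list(range(len(matrix.feature_labels)))
    steps = []
    while active:
        X = matrix.values[np.ix_(rows, active)]
        scored = _inner_cv_scores(X, y, config, rng)
        if scored is None:
            break
        for mt in (LOGISTIC, FOREST):
            auroc, aupr = scored[mt]
            steps.append(
                {
                    "model_type": mt,
                    "k": len(active),
                    "features": [matrix.feature_labels[j] for j in active],
                    "auroc": auroc,
                    "aupr": aupr,
                }
            )
        imp = scored["importances"]
        worst_local = max(
            (j for j in range(len(active))), key=lambda j: (-(imp[j]), j)
        )  # lowest importance; ties -> later column
        active.pop(worst_local)
    if not steps:
        raise ValueError("no scorable elimination step (degenerate training set)")
    tol = config.selection_tolerance
    max_auroc = max(s["auroc"] for s in steps)
    max_aupr = max(s["aupr"] for s in steps)
    qualifying = [
        s for s in steps if s["auroc"] >= tol * max_auroc and s["aupr"] >= tol * max_aupr
    ]
    logistic = [s for s in qualifying if s["model_type"] == LOGISTIC]
    pool = logistic if logistic else qualifying
    best = min(pool, key=lambda s: s["k"])
    return ModelSelection(
        model_type=best["model_type"],
        selected_features=best["features"],
        inner_scores=steps,
    )


def fit_and_predict(
    selection: ModelSelection,
    matrix: AggregatedFeatureMatrix,
    train_targets: list[str],
    train_labels: dict[str, str],
    test_targets: list[str],
    unlabeled_targets: list[str],
    config: CVConfig,
    rng: np.random.Generator,
    rep: int = 0,
    fold: int = 0,
) -> TrainTestCycle:
    """Refit the selected model on all training targets and emit probabilities.

    Targets missing from the aggregated matrix (a required feature was
    unavailable) get no prediction; the count is logged.
    """
    pos = {t: i for i, t in enumerate(matrix.targets)}
    cols = [matrix.feature_labels.index(f) for f in selection.selected_features]
    tr = [t for t in train_targets if t in pos]
    X_tr = matrix.values[np.ix_([pos[t] for t in tr], cols)]
    y_tr = np.array([train_labels[t] == SUCCESS for t in tr])
    model = _make_model(selection.model_type, config, int(rng.integers(2**31)))
    model.fit(X_tr, y_tr)

    def predict(targets: list[str]) -> dict[str, float]:
        avail = [t for t in targets if t in pos]
        if len(avail) < len(targets):
            log.debug("%d target(s) missing selected features", len(targets) - len(avail))
        if not avail:
            return {}
        P = model.predict_proba(matrix.values[np.ix_([pos[t] for t in avail], cols)])[:, 1]
        return dict(zip(avail, map(float, P)))

    return TrainTestCycle(
        rep=rep,
        fold=fold,
        selection=selection,
        test_predictions=predict(test_targets),
        unlabeled_predictions=predict(unlabeled_targets),
        model=model if config.keep_models else None,
        feature_medians=np.median(X_tr, axis=0) if config.keep_models else None,
    )


def outer_cv(
    datasets: list[ReducedDataset],
    labels: dict[str, str],
    class_map: dict[str, str],
    config: CVConfig,
) -> list[TrainTestCycle]:
    """Run the full nested cross-validation routine.

    Returns ``outer_reps x outer_folds`` cycles, including null-model cycles
    (no feature survived univariate selection) with empty predictions.
    """
    labeled = sorted(t for t, l in labels.items() if l in (SUCCESS, FAILURE))
    unlabeled = sorted(t for t, l in labels.items() if l == UNLABELED)
    y_all = np.array([labels[t] == SUCCESS for t in labeled])
    if y_all.sum() < config.outer_folds or (~y_all).sum() < config.outer_folds:
        raise ValueError("each outcome class must cover the outer folds")
    ds_by_name = {d.source.name: d for d in datasets}
    strata = build_strata(class_map)
    rng = np.random.default_rng(config.seed)
    labeled_arr = np.array(labeled)

    cycles: list[TrainTestCycle] = []
    for rep in range(config.outer_reps):
        skf = StratifiedKFold(
            n_splits=config.outer_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        for fold, (tr_idx, te_idx) in enumerate(skf.split(labeled_arr, y_all)):
            train_targets = list(labeled_arr[tr_idx])
            test_targets = list(labeled_arr[te_idx])
            train_labels = {t: labels[t] for t in train_targets}
            selected = {
                name: univariate_select(ds, train_labels, strata, config, rng)
                for name, ds in ds_by_name.items()
            }
            matrix = aggregate_features(
                selected,
                ds_by_name,
                train_targets,
                labeled + unlabeled,
                config,
                train_labels=train_labels,
            )
            if matrix is None or not matrix.feature_labels:
                log.info("rep %d fold %d: no significant features (null model)", rep, fold)
                cycles.append(TrainTestCycle(rep=rep, fold=fold, selection=None))
                continue
            selection = incremental_elimination(
                matrix, train_targets, train_labels, config, rng
            )
            cycles.append(
                fit_and_predict(
                    selection,
                    matrix,
                    train_targets,
                    train_labels,
                    test_targets,
                    unlabeled,
                    config,
                    rng,
                    rep=rep,
                    fold=fold,
                )
            )
    return cycles
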