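"""Performance statistics, prediction densities, cutoff scans, consistency.

Out-of-fold predictions from the nested-CV cycles are pooled per repetition
(each labeled target has one held-out prediction per repetition of the
outer 5-fold loop; unlabeled targets get up to one prediction per fold and
are averaged).  From the per-repetition prediction matrix this module
computes: the full panel of confusion/ranking statistics with 2.5/50/97.5
percentile summaries; kernel-density estimates of the predicted log-odds
with a change of variables back to the probability scale; probability
cutoffs maximising the median positive/negative predictive value; and the
pairwise ranking-consistency analysis (for an ordered target pair, the
fraction of repetitions in which one target's predicted success probability
strictly exceeds the other's).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.metrics import average_precision_score, roc_auc_score

from .crossval import TrainTestCycle
from .outcomes import SUCCESS

log = logging.getLogger(__name__)

PROB_CLIP = 1e-6  # keep log-odds finite
PERCENTILES = (2.5, 50.0, 97.5)

STATISTICS = (
    "TP", "FP", "TN", "FN",
    "TPR", "FPR", "FNR", "TNR",
    "MCR", "ACC", "FDR", "PPV", "FOMR", "NPV",
    "AUROC", "AUPR", "PLR", "NLR", "DOR", "RR", "MCC",
)


@dataclass
class PerformanceStats:
    per_repetition: pd.DataFrame  # repetitions x statistics
    summary: pd.DataFrame  # statistics x percentiles (2.5, 50, 97.5)
    threshold: float


@dataclass
class DensityEstimate:
    group: str
    bandwidth: float
    logodds_grid: np.ndarray
    logodds_density: np.ndarray
    probability_grid: np.ndarray
    probability_density: np.ndarray


@dataclass
class ConsistencyMatrix:
    targets: list[str]
    fraction: np.ndarray  # fraction[a, b] = frac of reps with P(b) > P(a)
    median_probability: np.ndarray


@dataclass
class CutoffScan:
    ppv_cutoff: float
    ppv_at_cutoff: float
    npv_cutoff: float
    npv_at_cutoff: float
    n_unlabeled_predicted_success: int
    n_unlabeled_predicted_failure: int
    npv_exceeds_reference_fraction: float
    reference_failure_rate: float


def _safe_div(a: float, b: float) -> float:
    return a / b if b else float("nan")


def confusion_statistics(y: np.ndarray, prob: np.ndarray, threshold: float) -> dict:
    """The full statistics panel for one repetition's pooled predictions."""
    pred = prob >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    tpr = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, fp + tn)
    tnr = _safe_div(tn, tn + fp)
    fnr = _safe_div(fn, fn + tp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    fomr = _safe_div(fn, fn + tn)
    fdr = _safe_div(fp, fp + tp)
    plr = _safe_div(tpr, fpr)
    nlr = _safe_div(fnr, tnr)
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return {
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "TPR": tpr, "FPR": fpr, "FNR": fnr, "TNR": tnr,
        "MCR": _safe_div(fp + fn, len(y)),
        "ACC": _safe_div(tp + tn, len(y)),
        "FDR": fdr, "PPV": ppv, "FOMR": fomr, "NPV": npv,
        "AUROC": float(roc_auc_score(y, prob)),
        "AUPR": float(average_precision_score(y, prob)),
        "PLR": plr,
        "NLR": nlr,
        "DOR": _safe_div(tp * tn, fp * fn),
        "RR": _safe_div(ppv, fomr),
        "MCC": _safe_div(tp * tn - fp * fn, mcc_den),
    }


def heldout_prediction_frame(cycles: list[TrainTestCycle]) -> pd.DataFrame:
    """Repetitions x labeled targets matrix of out-of-fold predictions.

    Each labeled target appears in exactly one test fold per repetition
    (possibly none, in a null-model cycle).
    """
    rows: dict[int, dict[str, float]] = {}
    for c in cycles:
        rows.setdefault(c.rep, {}).update(c.test_predictions)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def unlabeled_prediction_frame(cycles: list[TrainTestCycle]) -> pd.DataFrame:
    """Repetitions x unlabeled targets matrix, fold predictions averaged."""
    sums: dict[int, dict[str, list[float]]] = {}
    for c in cycles:
        d = sums.setdefault(c.rep, {})
        for t, p in c.unlabeled_predictions.items():
            d.setdefault(t, []).append(p)
    rows = {
        rep: {t: float(np.mean(ps)) for t, ps in d.items()} for rep, d in sums.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def repetition_stats(
    cycles: list[TrainTestCycle],
    labels: dict[str, str],
    threshold: float = 0.5,
) -> PerformanceStats:
    """Pool fold predictions per repetition and summarise the statistics.

    Repetitions whose pooled predictions cover only one outcome class are
    skipped with a warning.  The summary reports the 2.5th, 50th and 97.5th
    percentiles of each statistic across repetitions.
    """
    preds = heldout_prediction_frame(cycles)
    records = {}
    for rep, row in preds.iterrows():
        row = row.dropna()
        y = np.array([labels[t] == SUCCESS for t in row.index])
        if not y.any() or y.all():
            log.warning("repetition %s has a single outcome class; skipped", rep)
            continue
        records[rep] = confusion_statistics(y, row.to_numpy(float), threshold)
    per_rep = pd.DataFrame.from_dict(records, orient="index")[list(STATISTICS)]
    summary = per_rep.quantile([p / 100 for p in PERCENTILES]).T
    summary.columns = [f"p{p:g}" for p in PERCENTILES]
    return PerformanceStats(per_repetition=per_rep, summary=summary, threshold=threshold)


def probability_densities(
    predictions_by_group: dict[str, np.ndarray],
    n_grid: int = 512,
) -> list[DensityEstimate]:
    """Gaussian-kernel KDE of predicted log-odds, per target group.

    Probabilities are clipped into (0, 1) before the log-odds transform;
    the Silverman rule sets the bandwidth.  The probability-scale density is
    recovered with the change of variables |dy/dx| = 1/(x(1-x)), so it
    integrates to ~1 on (0, 1).  Groups with fewer than 3 values are
    skipped.
    """
    out = []
    for group, probs in predictions_by_group.items():
        probs = np.asarray(probs, dtype=float)
        probs = probs[np.isfinite(probs)]
        if probs.size < 3:
            log.warning("group %s has <3 predictions; density skipped", group)
            continue
        clipped = np.clip(probs, PROB_CLIP, 1 - PROB_CLIP)
        logodds = np.log(clipped / (1 - clipped))
        kde = gaussian_kde(logodds, bw_method="silverman")
        lo, hi = logodds.min(), logodds.max()
        pad = 3 * kde.factor * logodds.std(ddof=1) + 1e-9
        ygrid = np.linspace(lo - pad, hi + pad, n_grid)
        xgrid = np.linspace(PROB_CLIP, 1 - PROB_CLIP, n_grid)
        xlogodds = np.log(xgrid / (1 - xgrid))
        out.append(
            DensityEstimate(
                group=group,
                bandwidth=float(kde.factor * logodds.std(ddof=1)),
                logodds_grid=ygrid,
                logodds_density=kde(ygrid),
                probability_grid=xgrid,
                probability_density=kde(xlogodds) / (xgrid * (1 - xgrid)),
            )
        )
    return out


def cutoff_scan(
    rep_preds: pd.DataFrame,
    labels: dict[str, str],
    unlabeled_preds: pd.DataFrame | None = None,
    reference_failure_rate: float = 0.23,
) -> CutoffScan:
    """Scan probability cutoffs for the best median PPV and NPV.

    The candidate grid is the sorted unique observed probabilities.  At each
    cutoff, PPV (targets at or above the cutoff called successes) and NPV
    (targets below it called failures) are computed per repetition and the
    medians compared.  PPV ties resolve toward the cutoff classifying more
    targets positive (the smaller cutoff); NPV ties toward more targets
    negative (the larger cutoff).  Also reported: counts of unlabeled
    targets (by median prediction) beyond each chosen cutoff, and the
    fraction of repetitions whose NPV at the chosen cutoff exceeds the
    reference failure rate.
    """
    if len(rep_preds) < 2:
        raise ValueError("need at least two repetitions")
    values = rep_preds.to_numpy(float)
    y = np.array([labels[t] == SUCCESS for t in rep_preds.columns])
    grid = np.unique(values[np.isfinite(values)])
    median_ppv = np.full(len(grid), np.nan)
    median_npv = np.full(len(grid), np.nan)
    npv_per_rep_at = {}
    for i, cut in enumerate(grid):
        ppvs, npvs = [], []
        for r in range(values.shape[0]):
            row = values[r]
            ok = np.isfinite(row)
            pred = row[ok] >= cut
            yy = y[ok]
            tp, fp = (pred & yy).sum(), (pred & ~yy).sum()
            tn, fn = (~pred & ~yy).sum(), (~pred & yy).sum()
            ppvs.append(_safe_div(tp, tp + fp))
            npvs.append(_safe_div(tn, tn + fn))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cutoffs
            median_ppv[i] = np.nanmedian(ppvs)
            median_npv[i] = np.nanmedian(npvs)
        npv_per_rep_at[cut] = np.asarray(npvs, dtype=float)
    best_ppv = np.nanmax(median_ppv)
    ppv_cut = float(grid[np.flatnonzero(median_ppv == best_ppv)[0]])  # smallest
    best_npv = np.nanmax(median_npv)
    npv_cut = float(grid[np.flatnonzero(median_npv == best_npv)[-1]])  # largest
    npvs = npv_per_rep_at[npv_cut]
    exceeds = float(np.nanmean(npvs > reference_failure_rate)) if npvs.size else 0.0

    n_up = n_down = 0
    if unlabeled_preds is not None and not unlabeled_preds.empty:
        med = unlabeled_preds.median(axis=0)
        n_up = int((med >= ppv_cut).sum())
        n_down = int((med < npv_cut).sum())
    return CutoffScan(
        ppv_cutoff=ppv_cut,
        ppv_at_cutoff=float(best_ppv),
        npv_cutoff=npv_cut,
        npv_at_cutoff=float(best_npv),
        n_unlabeled_predicted_success=n_up,
        n_unlabeled_predicted_failure=n_down,
        npv_exceeds_reference_fraction=exceeds,
        reference_failure_rate=reference_failure_rate,
    )


def pairwise_consistency(rep_preds: pd.DataFrame) -> ConsistencyMatrix:
    """Ordered-pair ranking consistency across repetitions.

    ``fraction[a, b]`` is the fraction of repetitions in which target ``b``
    has a strictly higher predicted success probability than target ``a``;
    ties count for neither direction, so frac(a,b) + frac(b,a) <= 1 and the
    diagonal is 0.
    """
    values = rep_preds.to_numpy(float)
    n_reps = values.shape[0]
    greater = values[:, None, :] > values[:, :, None]  # (rep, a, b)
    fraction = greater.mean(axis=0)
    np.fill_diagonal(fraction, 0.0)
    return ConsistencyMatrix(
        targets=list(rep_preds.columns),
        fraction=fraction,
        median_probability=np.median(values, axis=0),
    )


def consistency_pair_counts(
    cm: ConsistencyMatrix,
    median_diff: float = 0.1,
    fold_change: float = 2.0,
    thresholds: tuple[float, ...] = (0.95, 0.99),
) -> pd.DataFrame:
    """Counts of ordered pairs passing separation and consistency rules.

    Separation rules: the median probability of the higher target exceeds
    the lower one's by at least ``median_diff``, or by at least a
    ``fold_change`` ratio.  Consistency rules: frac(a,b) at or above each
    threshold.  Rows: separation rule; columns: consistency threshold.
    """
    med = cm.median_probability
    diff_ok = (med[None, :] - med[:, None]) >= median_diff
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_ok = med[None, :] >= fold_change * med[:, None]
    np.fill_diagonal(diff_ok, False)
    np.fill_diagonal(fold_ok, False)
    rows = []
    for rule, ok in (("median_diff", diff_ok), ("fold_change", fold_ok)):
        rows.append(
            {
                "separation": rule,
                **{
                    f"consistency>={t:g}": int((ok & (cm.fraction >= t)).sum())
                    for t in thresholds
                },
            }
        )
    return pd.DataFrame(rows).set_index("separation")


def feature_projection_grid(
    cycles: list[TrainTestCycle],
    feature_pair: tuple[str, str],
    n_grid: int = 25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean predicted success probability over a two-feature plane.

    Uses cycles that kept their fitted model (``keep_models=True``) and
    whose selected features include both members of the pair; any other
    selected features are held at the cycle's training medians.  The grid
    spans [0, 1] in the min-max-scaled space of each feature.  Returns
    ``(x_grid, y_grid, mean_probability)`` with shape (n_grid, n_grid).
    """
    fa, fb = feature_pair
    x = np.linspace(0.0, 1.0, n_grid)
    xx, yy = np.meshgrid(x, x)
    total = np.zeros_like(xx)
    count = 0
    for c in cycles:
        if c.null_model or c.model is None:
            continue
        feats = c.selection.selected_features
        if fa not in feats or fb not in feats:
            continue
        grid_X = np.tile(c.feature_medians, (xx.size, 1))
        grid_X[:, feats.index(fa)] = xx.ravel()
        grid_X[:, feats.index(fb)] = yy.ravel()
        total += c.model.predict_proba(grid_X)[:, 1].reshape(xx.shape)
        count += 1
    if count == 0:
        log.warning("no cycle selected both %s and %s; empty grid", fa, fb)
        return xx, yy, np.full_like(xx, np.nan)
    return xx, yy, total / count


def projection_examples(
    matrix, labels: dict[str, str], feature_pair: tuple[str, str]
) -> dict[str, np.ndarray]:
    """Scaled (x, y) locations of success/failure examples for the plane.

    Companion to :func:`feature_projection_grid`: extracts, from an
    aggregated feature matrix, each labeled target's coordinates on the two
    projection features (min-max-scaled space), grouped by outcome.
    """
    cols = [matrix.feature_labels.index(f) for f in feature_pair]
    out: dict[str, list] = {}
    for i, t in enumerate(matrix.targets):
        label = labels.get(t)
        if label in ("success", "failure"):
            out.setdefault(label, []).append(matrix.values[i, cols])
    return {k: np.asarray(v) for k, v in out.items()}
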