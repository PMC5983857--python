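"""Bootstrap replication probabilities and target-class association tests.

Because clinically tested targets are not a random sample of the genome, a
feature that separates successes from failures in the observed sample may
not generalize.  Three resampling checks address this:

``bootstrap``
    plain bootstrap of the labeled targets; the replication probability of a
    feature is the fraction of resamples in which it stays significant at
    the within-dataset FDR threshold.
``class-holdout``
    bootstrap that excludes members of outcome-correlated target classes
    (e.g. a success-enriched GPCR-like class) from the resampling pool, so a
    finding driven purely by such a class cannot replicate.
``within-class-permutation``
    bootstrap in which each resample is re-screened against the
    within-class stratified permutation null, so features must correlate
    with outcome inside multiple classes.

Features with replication probability above 0.8 under a scheme are accepted
as robust/generalizable under that scheme.  Separate tests ask which target
classes are themselves correlated with outcome, and which significant
features those classes correlate with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dimreduce import ReducedDataset
from .outcomes import FAILURE, SUCCESS
from .permtest import (
    _strata_array,
    build_strata,
    by_adjust,
    perm_pvalues,
)

log = logging.getLogger(__name__)

BOOTSTRAP = "bootstrap"
CLASS_HOLDOUT = "class-holdout"
WITHIN_CLASS = "within-class-permutation"
SCHEMES = (BOOTSTRAP, CLASS_HOLDOUT, WITHIN_CLASS)

PASS_THRESHOLD = 0.8


@dataclass(frozen=True)
class ReplicationReport:
    feature_label: str
    scheme: str
    replication_probability: float
    n_boot: int
    pass_threshold: float
    n_redraws: int

    @property
    def passed(self) -> bool:
        return self.replication_probability > self.pass_threshold


@dataclass
class ClassAssociation:
    class_label: str
    n_members: int
    n_success: int
    observed_diff: float
    p_raw: float
    p_adj: float
    significant: bool
    sign: int
    correlated_features: list[tuple[str, int]] | None = None


@dataclass(frozen=True)
class ClassFeatureLink:
    class_label: str
    feature_label: str
    observed_diff: float
    p_adj: float
    significant: bool
    sign: int


def _labeled_pool(ds: ReducedDataset, labels: dict[str, str]) -> list[str]:
    return [g for g in ds.genes if labels.get(g) in (SUCCESS, FAILURE)]


def bootstrap_replication(
    ds: ReducedDataset,
    labels: dict[str, str],
    scheme: str = BOOTSTRAP,
    n_boot: int = 1000,
    alpha: float = 0.05,
    n_perm: int = 100_000,
    excluded_classes: tuple[str, ...] = (),
    class_map: dict[str, str] | None = None,
    pass_threshold: float = PASS_THRESHOLD,
    seed: int | np.random.Generator | None = None,
) -> list[ReplicationReport]:
    """Replication probability of every representative feature under a scheme.

    Each round resamples, with replacement, a set equal in size to the
    (possibly class-excluded) labeled pool, reruns the full within-dataset
    screen on the resample (same permutation count, same BY family — the
    dataset's complete representative feature list — and, for the
    within-class scheme, the same stratification), and records which
    features are significant.  Rounds with fewer than two of either outcome
    are redrawn; more than 10% redraws triggers a warning.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == CLASS_HOLDOUT and not excluded_classes:
        log.warning("class-holdout scheme with no excluded classes = plain bootstrap")
    if scheme in (CLASS_HOLDOUT, WITHIN_CLASS) and class_map is None:
        class_map = {}
    pool = _labeled_pool(ds, labels)
    if scheme == CLASS_HOLDOUT:
        pool = [g for g in pool if (class_map or {}).get(g) not in excluded_classes]
    y = np.array([labels[g] == SUCCESS for g in pool])
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two of each outcome after exclusions")
    rows = ds.gene_index(pool)
    X = ds.matrix[rows]
    strata_arr = None
    if scheme == WITHIN_CLASS:
        strata_arr = _strata_array(build_strata(class_map or {}), pool)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pool)
    sig_counts = np.zeros(ds.matrix.shape[1], dtype=int)
    redraws = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            y_b = y[idx]
            if y_b.sum() >= 2 and (~y_b).sum() >= 2:
                break
            redraws += 1
            log.debug("redrawing degenerate bootstrap round")
        strata_b = None if strata_arr is None else strata_arr[idx]
        _, p, _, _ = perm_pvalues(X[idx], y_b, n_perm, strata_b, rng)
        sig_counts += by_adjust(p) < alpha
    if redraws > 0.1 * n_boot:
        log.warning("%d/%d bootstrap rounds redrawn", redraws, n_boot)
    return [
        ReplicationReport(
            feature_label=lab,
            scheme=scheme,
            replication_probability=float(c / n_boot),
            n_boot=n_boot,
            pass_threshold=pass_threshold,
            n_redraws=redraws,
        )
        for lab, c in zip(ds.labels, sig_counts)
    ]


def class_outcome_tests(
    class_map: dict[str, str],
    labels: dict[str, str],
    alpha: float = 0.05,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> list[ClassAssociation]:
    """Test each target class's binary membership feature against outcome.

    Builds, over the labeled targets, one 0/1 membership vector per class
    and applies the same difference-of-means permutation test as the feature
    screen; BY adjustment treats all classes as a single family.  Classes
    with no labeled member are skipped with a warning.
    """
    labeled = sorted(t for t, l in labels.items() if l in (SUCCESS, FAILURE))
    y = np.array([labels[t] == SUCCESS for t in labeled])
    classes = sorted(set(class_map.values()))
    kept, columns = [], []
    for c in classes:
        member = np.array([class_map.get(t) == c for t in labeled], dtype=float)
        if member.sum() == 0:
            log.warning("class %s has no labeled member; skipped", c)
            continue
        kept.append(c)
        columns.append(member)
    if not kept:
        return []
    X = np.column_stack(columns)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs, p, _, _ = perm_pvalues(X, y, n_perm, None, rng)
    p_adj = by_adjust(p)
    out = []
    for j, c in enumerate(kept):
        members = X[:, j] > 0
        out.append(
            ClassAssociation(
                class_label=c,
                n_members=int(members.sum()),
                n_success=int((members & y).sum()),
                observed_diff=float(obs[j]),
                p_raw=float(p[j]),
                p_adj=float(p_adj[j]),
                significant=bool(p_adj[j] < alpha),
                sign=int(np.sign(obs[j])),
            )
        )
    return out


def class_feature_tests(
    significant_classes: list[str],
    ds: ReducedDataset,
    significant_features: list[str],
    class_map: dict[str, str],
    labels: dict[str, str],
    alpha: float = 0.05,
    n_perm: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> list[ClassFeatureLink]:
    """Test outcome-correlated classes against outcome-correlated features.

    For each (class, feature) pair the statistic is the feature's mean
    difference between class members and non-members among the labeled
    targets, assessed by permuting membership; BY adjustment spans all pairs
    as one family.  The sign is + when members run high.
    """
    if not significant_classes or not significant_features:
        return []
    pool = _labeled_pool(ds, labels)
    rows = ds.gene_index(pool)
    cols = [ds.labels.index(f) for f in significant_features]
    X = ds.matrix[rows][:, cols]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_obs, all_p, pairs = [], [], []
    for c in significant_classes:
        member = np.array([class_map.get(t) == c for t in pool])
        if member.sum() == 0 or member.all():
            log.warning("class %s degenerate among labeled targets; skipped", c)
            continue
        obs, p, _, _ = perm_pvalues(X, member, n_perm, None, rng)
        for f, o, pv in zip(significant_features, obs, p):
            pairs.append((c, f))
            all_obs.append(float(o))
            all_p.append(float(pv))
    if not pairs:
        return []
    p_adj = by_adjust(all_p)
    return [
        ClassFeatureLink(
            class_label=c,
            feature_label=f,
            observed_diff=o,
            p_adj=float(pa),
            significant=bool(pa < alpha),
            sign=int(np.sign(o)),
        )
        for (c, f), o, pa in zip(pairs, all_obs, p_adj)
    ]
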