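"""Permutation tests for outcome association, with stratified nulls and BY FDR.

The test statistic for every feature is the difference between the mean of
the successful targets and the mean of the failed targets.  Significance is
assessed against an empirical null built by shuffling the success/failure
labels — either freely, or only *within target-class strata* so that the
ratio of successes to failures inside each class is preserved and features
that merely discriminate between classes cannot appear significant.  When
the number of distinct labelings is small enough, the null is enumerated
exhaustively instead of sampled.  P-values are adjusted per dataset with the
Benjamini-Yekutieli procedure, which controls the FDR under arbitrary
dependence between features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dimreduce import ReducedDataset
from .outcomes import FAILURE, SUCCESS

log = logging.getLogger(__name__)

_TOL = 1e-12  # absolute slack when comparing permuted |stat| to observed |stat|

POOLED_STRATUM = "pooled-stratum"
OWN_STRATUM = "own-stratum"


class ConfigurationError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationResult:
    feature_label: str
    observed_diff: float
    p_raw: float
    p_adj: float
    significant: bool
    n_perm: int
    exact: bool  # null enumerated exhaustively rather than sampled
    sign: int


@dataclass
class StratifiedNullSpec:
    """Target-class strata for the within-class permutation null.

    ``strata`` maps a target to its class; targets absent from the map are
    unclassified and, under the default ``pooled-stratum`` policy, form one
    shared stratum (``own-stratum`` would instead freeze each unclassified
    target's label, destroying power).
    """

    strata: dict[str, str]
    unclassified_policy: str = POOLED_STRATUM

    def stratum_of(self, target: str) -> str:
        if target in self.strata:
            return self.strata[target]
        if self.unclassified_policy == POOLED_STRATUM:
            return "__unclassified__"
        return f"__own__{target}"


def diff_of_means(values: np.ndarray, y: np.ndarray) -> float:
    """mean(success values) - mean(failure values).

    ``y`` is a boolean success indicator aligned with ``values``.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    if not y.any() or y.all():
        raise UndefinedStatisticError("need at least one success and one failure")
    return float(values[y].mean() - values[~y].mean())


def _stratum_codes(strata: np.ndarray | None, n: int) -> np.ndarray:
    if strata is None:
        return np.zeros(n, dtype=int)
    _, codes = np.unique(np.asarray(strata), return_inverse=True)
    return codes


def _n_labelings(codes: np.ndarray, y: np.ndarray) -> int:
    total = 1
    for s in np.unique(codes):
        idx = codes == s
        total *= math.comb(int(idx.sum()), int(y[idx].sum()))
        if total > 10**18:
            return total
    return total


def _enumerate_labelings(codes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All label assignments preserving the per-stratum success count."""
    strata_ids = np.unique(codes)
    per_stratum = []
    for s in strata_ids:
        idx = np.flatnonzero(codes == s)
        k = int(y[idx].sum())
        per_stratum.append([idx[list(c)] for c in combinations(range(len(idx)), k)])
    rows = []
    for combo in product(*per_stratum):
        row = np.zeros(len(y), dtype=bool)
        for chosen in combo:
            row[chosen] = True
        rows.append(row)
    return np.array(rows)


def _sample_labelings(
    codes: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    perms = np.empty((n_perm, len(y)), dtype=bool)
    for s in np.unique(codes):
        idx = np.flatnonzero(codes == s)
        keys = rng.random((n_perm, len(idx)))
        order = np.argsort(keys, axis=1)
        perms[:, idx] = np.asarray(y, dtype=bool)[idx][order]
    return perms


def null_labelings(
    y: np.ndarray,
    n_perm: int,
    strata: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    force_monte_carlo: bool = False,
) -> tuple[np.ndarray, bool]:
    """Permuted success-indicator matrix ``(P, n)`` and an exactness flag.

    If the number of distinct labelings (product of per-stratum binomial
    coefficients) does not exceed ``n_perm`` the full set is enumerated and
    the resulting p-values are exact; otherwise ``n_perm`` within-stratum
    shuffles are sampled.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be at least 1")
    y = np.asarray(y, dtype=bool)
    codes = _stratum_codes(strata, len(y))
    if not force_monte_carlo and _n_labelings(codes, y) <= n_perm:
        return _enumerate_labelings(codes, y), True
    if rng is None:
        rng = np.random.default_rng()
    return _sample_labelings(codes, y, n_perm, rng), False


def perm_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    strata: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    force_monte_carlo: bool = False,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Observed difference-of-means and empirical two-tailed p per column.

    One permutation set is drawn per call and shared by all columns of ``X``.
    Monte-Carlo p-values use the add-one convention
    ``p = (1 + #extreme) / (1 + P)`` so they are never zero and the test
    remains valid; enumerated p-values are plain fractions (the observed
    labeling is one of the enumerated ones, so they are already positive).

    Returns ``(observed, p, n_used, exact)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=bool)
    if not y.any() or y.all():
        raise UndefinedStatisticError("need at least one success and one failure")
    perms, exact = null_labelings(y, n_perm, strata, rng, force_monte_carlo)
    n_s = perms[0].sum()
    n_f = len(y) - n_s
    observed = X[y].mean(axis=0) - X[~y].mean(axis=0)
    null = (perms @ X) / n_s - ((~perms) @ X) / n_f
    extreme = (np.abs(null) >= np.abs(observed)[None, :] - _TOL).sum(axis=0)
    if exact:
        p = extreme / len(perms)
    else:
        p = (1 + extreme) / (1 + len(perms))
    return observed, p, len(perms), exact


def permutation_test(
    values: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    strata: np.ndarray | None = None,
    rng_seed: int | np.random.Generator | None = None,
    feature_label: str = "feature",
    force_monte_carlo: bool = False,
) -> PermutationResult:
    """Permutation test of one feature; see :func:`perm_pvalues`."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    obs, p, n_used, exact = perm_pvalues(
        np.asarray(values, dtype=float).reshape(-1, 1),
        y,
        n_perm,
        strata,
        rng,
        force_monte_carlo,
    )
    return PermutationResult(
        feature_label=feature_label,
        observed_diff=float(obs[0]),
        p_raw=float(p[0]),
        p_adj=float(p[0]),
        significant=False,
        n_perm=n_used,
        exact=exact,
        sign=int(np.sign(obs[0])),
    )


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under dependence)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _strata_array(
    spec: StratifiedNullSpec | None, targets: list[str]
) -> np.ndarray | None:
    if spec is None:
        return None
    return np.array([spec.stratum_of(t) for t in targets])


def build_strata(
    class_map: dict[str, str], unclassified_policy: str = POOLED_STRATUM
) -> StratifiedNullSpec:
    """Stratification spec from a target -> class map."""
    return StratifiedNullSpec(dict(class_map), unclassified_policy)


def screen_dataset(
    ds: ReducedDataset,
    labels: dict[str, str],
    alpha: float = 0.05,
    n_perm: int = 100_000,
    strata: StratifiedNullSpec | None = None,
    seed: int | np.random.Generator | None = None,
    force_monte_carlo: bool = False,
) -> list[PermutationResult]:
    """Screen every representative feature of a reduced dataset.

    Targets are the dataset genes carrying a success/failure label; BY
    adjustment is applied within this dataset only, and a feature is called
    significant when its adjusted p-value is below ``alpha``.
    """
    labeled = [g for g in ds.genes if labels.get(g) in (SUCCESS, FAILURE)]
    if not ds.groups or not labeled:
        return []
    rows = ds.gene_index(labeled)
    X = ds.matrix[rows]
    y = np.array([labels[g] == SUCCESS for g in labeled])
    strata_arr = _strata_array(strata, labeled)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs, p, n_used, exact = perm_pvalues(
        X, y, n_perm, strata_arr, rng, force_monte_carlo
    )
    p_adj = by_adjust(p)
    return [
        PermutationResult(
            feature_label=lab,
            observed_diff=float(o),
            p_raw=float(pr),
            p_adj=float(pa),
            significant=bool(pa < alpha),
            n_perm=n_used,
            exact=exact,
            sign=int(np.sign(o)),
        )
        for lab, o, pr, pa in zip(ds.labels, obs, p, p_adj)
    ]
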