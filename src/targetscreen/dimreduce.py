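"""Correlation-based feature grouping with interpretable representatives.

Rather than projecting onto abstract components, groups of mutually
correlated features (squared pairwise association >= a threshold, 0.5 by
default) are replaced by a single representative: the group mean labeled by
the group's seed feature, or the dataset-wide ``mean`` summary feature if it
falls inside the group.  Association is Spearman's rank correlation for
quantitative filled-in datasets and the cosine coefficient for sparse or
categorical ones (for which r^2 = 0.5 corresponds to two features aligned
within 45 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MEAN_LABEL, QUANT_FILLED, GeneFeatureDataset


@dataclass
class FeatureGroup:
    representative_label: str
    member_labels: list[str]
    values: np.ndarray
    is_dataset_mean: bool = False
    member_r2: list[float] | None = None  # squared association to the seed


@dataclass
class ReducedDataset:
    """A dataset after redundancy reduction: one column per feature group."""

    source: GeneFeatureDataset
    groups: list[FeatureGroup]

    @property
    def genes(self) -> list[str]:
        return self.source.genes

    @property
    def labels(self) -> list[str]:
        return [g.representative_label for g in self.groups]

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([g.values for g in self.groups])

    def gene_index(self, targets) -> np.ndarray:
        return self.source.gene_index(targets)

    def group_table(self) -> pd.DataFrame:
        """Group membership table (representative, members, r^2 to the seed)."""
        rows = []
        for g in self.groups:
            r2 = g.member_r2 or [np.nan] * len(g.member_labels)
            rows.append(
                {
                    "representative": g.representative_label,
                    "is_dataset_mean": g.is_dataset_mean,
                    "n_members": len(g.member_labels),
                    "members": "|".join(g.member_labels),
                    "member_r2": "|".join(f"{v:.3f}" for v in r2),
                }
            )
        return pd.DataFrame(rows)


def cosine_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise cosine coefficients between columns; zero vectors give 0."""
    norms = np.linalg.norm(values, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = values / safe
    sim = unit.T @ unit
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def pairwise_association(ds: GeneFeatureDataset) -> np.ndarray:
    """Feature x feature association matrix, by dataset kind.

    Spearman correlation for quantitative filled-in data, cosine coefficient
    for sparse/categorical data.  Symmetric with unit diagonal; undefined
    entries (constant columns under Spearman) are set to 0.
    """
    if ds.n_features < 2:
        raise ValueError(f"{ds.name}: need at least two features")
    if ds.kind == QUANT_FILLED:
        r = np.asarray(stats.spearmanr(ds.values).statistic, dtype=float)
        if r.ndim == 0:  # scipy collapses the two-feature case to a scalar
            r = np.array([[1.0, float(r)], [float(r), 1.0]])
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
        return r
    return cosine_matrix(ds.values)


def reduce_features(
    ds: GeneFeatureDataset,
    r2_threshold: float = 0.5,
    association: np.ndarray | None = None,
) -> ReducedDataset:
    """Greedy correlation grouping at squared association >= ``r2_threshold``.

    Features are ordered by decreasing number of correlated partners (ties:
    original column order).  Each seed absorbs its not-yet-grouped partners;
    membership always refers back to the original association matrix, never
    to recomputed correlations against group means.  A group containing the
    dataset ``mean`` summary feature is represented by the dataset mean
    itself; any other group is represented by the plain average of its
    members, labeled by the seed.
    """
    if ds.n_features == 0:
        return ReducedDataset(source=ds, groups=[])
    if ds.n_features == 1:
        return ReducedDataset(
            source=ds,
            groups=[
                FeatureGroup(
                    representative_label=ds.feature_labels[0],
                    member_labels=list(ds.feature_labels),
                    values=ds.values[:, 0].copy(),
                    is_dataset_mean=ds.feature_labels[0] == MEAN_LABEL,
                    member_r2=[1.0],
                )
            ],
        )
    r = pairwise_association(ds) if association is None else association
    r2 = r**2
    adjacent = r2 >= r2_threshold
    np.fill_diagonal(adjacent, False)
    counts = adjacent.sum(axis=0)
    order = np.argsort(-counts, kind="stable")

    mean_idx = (
        ds.feature_labels.index(MEAN_LABEL) if MEAN_LABEL in ds.feature_labels else -1
    )
    assigned = np.zeros(ds.n_features, dtype=bool)
    groups: list[FeatureGroup] = []
    for seed in order:
        if assigned[seed]:
            continue
        members = [seed] + [
            j for j in np.flatnonzero(adjacent[seed]) if not assigned[j]
        ]
        assigned[members] = True
        member_labels = [ds.feature_labels[j] for j in members]
        member_r2 = [float(r2[seed, j]) for j in members]
        if mean_idx in members:
            groups.append(
                FeatureGroup(
                    representative_label=MEAN_LABEL,
                    member_labels=member_labels,
                    values=ds.values[:, mean_idx].copy(),
                    is_dataset_mean=True,
                    member_r2=member_r2,
                )
            )
        else:
            groups.append(
                FeatureGroup(
                    representative_label=ds.feature_labels[seed],
                    member_labels=member_labels,
                    values=ds.values[:, members].mean(axis=1),
                    member_r2=member_r2,
                )
            )
    return ReducedDataset(source=ds, groups=groups)
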