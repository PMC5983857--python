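"""Gene x feature matrices: IO, standardization, summary features, coverage.

Each omics dataset is a matrix with genes on the rows and features (tissues,
pathways, diseases, ...) on the columns, in one of three value shapes:

``quantitative-filled``
    dense continuous values (e.g. microarray expression); columns are
    z-scored (mean 0, SD 1).
``quantitative-sparse``
    continuous values with structural zeros meaning "absent" (e.g. IHC
    protein expression); columns are scaled to mean 1, preserving zeros.
``categorical-sparse``
    binary membership values (e.g. curated pathway annotations); left
    unchanged.

Per-gene row summaries (mean, SD across the dataset's columns) are appended
as extra features, as is an optional expression-entropy feature computed on
the raw (pre-standardization) values.  Features with fewer than three
non-zero values among outcome-labeled targets are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

QUANT_FILLED = "quantitative-filled"
QUANT_SPARSE = "quantitative-sparse"
CATEGORICAL = "categorical-sparse"
KINDS = (QUANT_FILLED, QUANT_SPARSE, CATEGORICAL)

MEAN_LABEL = "mean"
STDV_LABEL = "stdv"
ENTROPY_LABEL = "entropy"


class DatasetError(ValueError):
    """Raised for malformed gene-feature datasets."""


@dataclass
class GeneFeatureDataset:
    """One omics dataset as a gene x feature matrix.

    ``raw_values`` keeps the pre-standardization values, column-aligned with
    ``values`` (appended summary columns are mirrored there so the two
    matrices always share shape); ``appended`` records which columns are
    derived summaries rather than original dataset features.
    """

    name: str
    kind: str
    genes: list[str]
    feature_labels: list[str]
    values: np.ndarray
    raw_values: np.ndarray | None = None
    is_human: bool = True
    n_genes_total: int | None = None
    appended: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DatasetError(f"unknown dataset kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.feature_labels)):
            raise DatasetError(
                f"{self.name}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.feature_labels)} features"
            )
        if self.n_genes_total is None:
            self.n_genes_total = len(self.genes)

    @property
    def n_features(self) -> int:
        return len(self.feature_labels)

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.feature_labels.index(label)]

    def gene_index(self, targets: Iterable[str]) -> np.ndarray:
        """Row indices of ``targets`` that are present in this dataset."""
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array([pos[t] for t in targets if t in pos], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.feature_labels)


def _keep_columns(ds: GeneFeatureDataset, keep: np.ndarray) -> GeneFeatureDataset:
    labels = [l for l, k in zip(ds.feature_labels, keep) if k]
    return replace(
        ds,
        feature_labels=labels,
        values=ds.values[:, keep],
        raw_values=None if ds.raw_values is None else ds.raw_values[:, keep],
        appended=[l for l in ds.appended if l in labels],
    )


def standardize(ds: GeneFeatureDataset) -> GeneFeatureDataset:
    """Kind-specific column standardization; keeps a raw-value copy.

    quantitative-filled columns are z-scored (population SD, so a column
    like ``[1, 2, 3]`` maps to ``[-1.2247, 0, 1.2247]``); quantitative-sparse
    columns are divided by their mean (zeros stay zero, column mean becomes
    1); categorical columns pass through.  Degenerate columns (zero variance
    for the filled kind, zero mean for the sparse kind) are dropped with a
    warning.
    """
    values = ds.values
    if ds.kind == QUANT_FILLED and not np.all(np.isfinite(values)):
        raise DatasetError(f"{ds.name}: non-finite values in quantitative data")
    raw = values.copy() if ds.raw_values is None else ds.raw_values.copy()
    out = replace(ds, raw_values=raw)
    if ds.kind == CATEGORICAL:
        bad = ~np.isin(values, (0.0, 1.0)).all(axis=0)
        if bad.any():
            raise DatasetError(
                f"{ds.name}: non-binary categorical columns "
                f"{[l for l, b in zip(ds.feature_labels, bad) if b]}"
            )
        return out
    if ds.kind == QUANT_FILLED:
        sd = values.std(axis=0)
        keep = sd > 0
        if not keep.all():
            log.warning(
                "%s: dropping %d zero-variance column(s)", ds.name, (~keep).sum()
            )
            out = _keep_columns(out, keep)
            values, sd = out.values, sd[keep]
        z = (values - values.mean(axis=0)) / sd
        return replace(out, values=z)
    # quantitative-sparse: nonzero-preserving scaling to column mean 1
    mean = values.mean(axis=0)
    keep = mean != 0
    if not keep.all():
        log.warning("%s: dropping %d zero-mean column(s)", ds.name, (~keep).sum())
        out = _keep_columns(out, keep)
        values, mean = out.values, mean[keep]
    return replace(out, values=values / mean)


def _append(ds: GeneFeatureDataset, label: str, column: np.ndarray) -> GeneFeatureDataset:
    if label in ds.feature_labels:
        raise DatasetError(f"{ds.name}: feature {label!r} already present")
    column = column.reshape(-1, 1)
    raw = ds.raw_values
    return replace(
        ds,
        feature_labels=ds.feature_labels + [label],
        values=np.hstack([ds.values, column]),
        raw_values=None if raw is None else np.hstack([raw, column]),
        appended=ds.appended + [label],
    )


def append_row_summaries(ds: GeneFeatureDataset) -> GeneFeatureDataset:
    """Append per-gene ``mean`` and ``stdv`` (sample SD) across the columns.

    Computed on the standardized values, over the dataset's original feature
    columns (previously appended summaries are excluded).  With a single
    feature column the SD is undefined and the ``stdv`` column is omitted.
    """
    original = [i for i, l in enumerate(ds.feature_labels) if l not in ds.appended]
    block = ds.values[:, original]
    out = _append(ds, MEAN_LABEL, block.mean(axis=1))
    if len(original) < 2:
        log.warning("%s: single feature column, omitting 'stdv' summary", ds.name)
        return out
    return _append(out, STDV_LABEL, block.std(axis=1, ddof=1))


def append_entropy(ds: GeneFeatureDataset) -> GeneFeatureDataset:
    """Append the per-gene expression entropy H = sum P_i log2(1/P_i).

    P_i = E_i / sum(E_i) where E_i are the *raw* (un-log-transformed,
    pre-standardization) values of the dataset's original feature columns;
    low entropy means tissue-specific expression.  Rows summing to zero get
    entropy 0.  Intended for expression-kind datasets; negative raw values
    are rejected.
    """
    if ds.raw_values is None:
        raise DatasetError(f"{ds.name}: raw values required for entropy")
    original = [i for i, l in enumerate(ds.feature_labels) if l not in ds.appended]
    raw = ds.raw_values[:, original]
    if (raw < 0).any():
        raise DatasetError(f"{ds.name}: negative raw values; entropy undefined")
    totals = raw.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, raw / np.where(totals > 0, totals, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return _append(ds, ENTROPY_LABEL, -plogp.sum(axis=1))


def coverage_filter(
    ds: GeneFeatureDataset, labeled_targets: Sequence[str]
) -> GeneFeatureDataset:
    """Drop features with fewer than three non-zero values among labeled targets.

    Only labeled targets present in the dataset contribute; "non-zero" is an
    exact comparison (stored zeros are absences for the sparse kinds, and
    standardized filled values are essentially never exactly zero).
    """
    rows = ds.gene_index(labeled_targets)
    counts = (
        np.count_nonzero(ds.values[rows], axis=0)
        if rows.size
        else np.zeros(ds.n_features, dtype=int)
    )
    keep = counts >= 3
    if not keep.all():
        log.info("%s: coverage filter dropped %d feature(s)", ds.name, (~keep).sum())
    return _keep_columns(ds, keep)


# ---------------------------------------------------------------------------
# Tab-delimited IO
# ---------------------------------------------------------------------------

def read_gene_feature_tsv(
    path: str | Path,
    kind: str,
    name: str | None = None,
    is_human: bool = True,
    n_genes_total: int | None = None,
) -> GeneFeatureDataset:
    """Read a gene-attribute matrix TSV.

    Layout: header line, then one row per gene with the gene symbol in the
    first column, a gene identifier in the second, and numeric feature values
    in the rest.  A dialect with two extra ``#``-prefixed header lines
    (feature identifiers / metadata, as in "cleaned" gene-attribute exports)
    is also accepted and the extra lines are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    symbols = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    return GeneFeatureDataset(
        name=name or path.stem,
        kind=kind,
        genes=symbols,
        feature_labels=[str(c) for c in df.columns[2:]],
        values=values,
        is_human=is_human,
        n_genes_total=n_genes_total,
    )


def write_gene_feature_tsv(ds: GeneFeatureDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.values, columns=ds.feature_labels)
    df.insert(0, "gene_id", ds.genes)
    df.insert(0, "gene_symbol", ds.genes)
    df.to_csv(path, sep="\t", index=False)
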