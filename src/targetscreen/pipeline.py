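"""Convenience wiring of the per-stage operations into the standard pipeline.

The canonical flow per dataset is

    standardize -> append_row_summaries [-> append_entropy]
                -> coverage_filter -> reduce_features

over targets labeled from the filtered asset table.  These helpers run that
flow and reload a study directory written by the synthetic generator (or
assembled by hand in the same layout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import outcomes as oc
from .datasets import (
    GeneFeatureDataset,
    append_entropy,
    append_row_summaries,
    coverage_filter,
    read_gene_feature_tsv,
    standardize,
)
from .dimreduce import ReducedDataset, reduce_features


@dataclass
class Study:
    """A loaded study: asset records, labels, datasets, class map."""

    asset_table: list[oc.AssetRecord]
    outcomes: list[oc.TargetOutcome]
    summary: oc.OutcomeSummary
    labels: dict[str, str]
    datasets: list[GeneFeatureDataset]
    class_map: dict[str, str]


def prepare_dataset(
    ds: GeneFeatureDataset,
    labeled_targets: list[str],
    with_entropy: bool = False,
    r2_threshold: float = 0.5,
) -> ReducedDataset:
    """Standardize, append summaries, coverage-filter and reduce one dataset."""
    ds = standardize(ds)
    ds = append_row_summaries(ds)
    if with_entropy:
        ds = append_entropy(ds)
    ds = coverage_filter(ds, labeled_targets)
    return reduce_features(ds, r2_threshold=r2_threshold)


def score_study_outcomes(
    asset_table: list[oc.AssetRecord], universe: list[str]
) -> tuple[list[oc.TargetOutcome], oc.OutcomeSummary]:
    """Filter asset records and score the target universe."""
    return oc.score_targets(oc.filter_assets(asset_table), universe)


def load_study_dir(path: str | Path) -> Study:
    """Load a study directory (assets.tsv, class_map.tsv, manifest.json, data)."""
    path = Path(path)
    asset_table = oc.read_assets(path / "assets.tsv")
    class_map = (
        oc.read_class_map(path / "class_map.tsv")
        if (path / "class_map.tsv").exists()
        else {}
    )
    manifest = json.loads((path / "manifest.json").read_text())
    datasets = [
        read_gene_feature_tsv(
            path / entry["file"],
            kind=entry["kind"],
            name=entry["name"],
            is_human=entry.get("is_human", True),
            n_genes_total=entry.get("n_genes_total"),
        )
        for entry in manifest["datasets"]
    ]
    universe = sorted({g for ds in datasets for g in ds.genes})
    outcomes, summary = score_study_outcomes(asset_table, universe)
    return Study(
        asset_table=asset_table,
        outcomes=outcomes,
        summary=summary,
        labels=oc.label_map(outcomes),
        datasets=datasets,
        class_map=class_map,
    )


def labeled_targets(labels: dict[str, str]) -> list[str]:
    return sorted(t for t, l in labels.items() if l in (oc.SUCCESS, oc.FAILURE))
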