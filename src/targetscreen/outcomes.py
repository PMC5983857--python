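"""Clinical outcome filtering and per-target outcome scoring.

The unit of analysis is the drug *target* (a gene/protein), not the drug
asset.  Asset-level records (one row per drug candidate / indication) are
first filtered down to the informative slice — selective (single-target)
drugs against human targets and non-cancer indications, with a definitive
phase III outcome — and each target is then scored by its best remaining
outcome: any approval makes it a success; otherwise any phase III failure
makes it a failure; targets with no qualifying record stay unlabeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: The outcome vocabulary for asset-indication records.
OUTCOMES = (
    "Succeeded",
    "InProgress-Preclinical",
    "InProgress-PhaseI",
    "InProgress-PhaseII",
    "InProgress-PhaseIII",
    "Failed-Preclinical",
    "Failed-PhaseI",
    "Failed-PhaseII",
    "Failed-PhaseIII",
    "Failed-Withdrawn",
)

#: Outcomes that count toward a target's phase III success/failure label.
QUALIFYING_OUTCOMES = frozenset({"Succeeded", "Failed-PhaseIII"})

SUCCESS = "success"
FAILURE = "failure"
UNLABELED = "unlabeled"


class ValidationError(ValueError):
    """Raised for malformed asset records or outcome tables."""


@dataclass(frozen=True)
class AssetRecord:
    """One asset (drug or drug candidate) tested against one indication."""

    asset_id: str
    target_ids: tuple[str, ...]
    indication: str
    indication_class: str  # e.g. "cancer" vs "other"
    outcome: str
    target_species: str = "human"


@dataclass(frozen=True)
class TargetOutcome:
    target_id: str
    label: str  # success | failure | unlabeled


@dataclass(frozen=True)
class OutcomeSummary:
    n_success: int
    n_fail: int

    @property
    def success_rate(self) -> float:
        n = self.n_success + self.n_fail
        return self.n_success / n if n else float("nan")


def filter_assets(records: Iterable[AssetRecord]) -> list[AssetRecord]:
    """Keep records eligible for target outcome scoring.

    Retains records with exactly one target, a human target, a non-cancer
    indication, and a definitive phase III outcome (``Succeeded`` or
    ``Failed-PhaseIII``).  Order-preserving and idempotent.

    Raises
    ------
    ValidationError
        If any record lists no target at all.
    """
    records = list(records)
    orphans = [r.asset_id for r in records if len(r.target_ids) == 0]
    if orphans:
        raise ValidationError(f"asset records without a target: {orphans}")
    return [
        r
        for r in records
        if len(r.target_ids) == 1
        and r.target_species == "human"
        and r.indication_class.lower() != "cancer"
        and r.outcome in QUALIFYING_OUTCOMES
    ]


def score_targets(
    records: Sequence[AssetRecord], universe: Sequence[str]
) -> tuple[list[TargetOutcome], OutcomeSummary]:
    """Score each target in ``universe`` by its best qualifying outcome.

    ``records`` should already have passed :func:`filter_assets`.  A target
    with at least one ``Succeeded`` record is a success regardless of how
    many failures it also has (best-outcome-wins); with no successes and at
    least one ``Failed-PhaseIII`` record it is a failure; otherwise it is
    unlabeled.
    """
    succeeded: set[str] = set()
    failed: set[str] = set()
    for r in records:
        (target,) = r.target_ids
        if r.outcome == "Succeeded":
            succeeded.add(target)
        elif r.outcome == "Failed-PhaseIII":
            failed.add(target)
    outcomes = []
    for t in universe:
        if t in succeeded:
            label = SUCCESS
        elif t in failed:
            label = FAILURE
        else:
            label = UNLABELED
        outcomes.append(TargetOutcome(t, label))
    n_s = sum(o.label == SUCCESS for o in outcomes)
    n_f = sum(o.label == FAILURE for o in outcomes)
    return outcomes, OutcomeSummary(n_s, n_f)


def label_map(outcomes: Iterable[TargetOutcome]) -> dict[str, str]:
    """Target -> label dictionary from a list of :class:`TargetOutcome`."""
    return {o.target_id: o.label for o in outcomes}


# ---------------------------------------------------------------------------
# Tab-delimited IO
# ---------------------------------------------------------------------------

ASSET_COLUMNS = [
    "asset_id",
    "target_ids",
    "indication",
    "indication_class",
    "outcome",
    "target_species",
]


def read_assets(path: str | Path) -> list[AssetRecord]:
    """Read an asset table (TSV with :data:`ASSET_COLUMNS` header).

    ``target_ids`` holds ``|``-separated gene identifiers; an empty field
    means the record has no target and triggers a validation error downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ASSET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"asset table {path} lacks columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        targets = tuple(t for t in str(row.target_ids).split("|") if t)
        records.append(
            AssetRecord(
                asset_id=row.asset_id,
                target_ids=targets,
                indication=row.indication,
                indication_class=row.indication_class,
                outcome=row.outcome,
                target_species=row.target_species or "human",
            )
        )
    return records


def write_assets(records: Iterable[AssetRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "asset_id": r.asset_id,
                "target_ids": "|".join(r.target_ids),
                "indication": r.indication,
                "indication_class": r.indication_class,
                "outcome": r.outcome,
                "target_species": r.target_species,
            }
            for r in records
        ],
        columns=ASSET_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_outcomes(path: str | Path) -> list[TargetOutcome]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TargetOutcome(r.target_id, r.label) for r in df.itertuples(index=False)]


def write_outcomes(outcomes: Iterable[TargetOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [(o.target_id, o.label) for o in outcomes], columns=["target_id", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a target-class (gene family) membership TSV (target_id, class).

    A target listed under several classes keeps its first listed class, so
    the map is a partition of the classified targets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, str] = {}
    for target, cls in df.itertuples(index=False, name=None):
        mapping.setdefault(target, cls)
    return mapping


def write_class_map(class_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(class_map.items()), columns=["target_id", "class"]
    ).to_csv(path, sep="\t", index=False)
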