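"""Synthetic studies with planted structure for end-to-end testing.

Generates the three inputs the screening pipeline consumes — an asset-level
clinical-outcome table, one or more gene x feature matrices, and a
target-class membership map — with known ground truth:

* outcome effects planted on a dataset's per-gene row mean, row SD, or a
  named feature, expressed as a shift of the success-vs-failure group means
  in pooled-SD units (the headline real-data finding this emulates is lower
  mean and higher dispersion of tissue expression among successful targets);
* blocks of correlated features whose pairwise squared correlation matches
  a configured r^2;
* confounded target classes with configured success rates (e.g. a
  success-enriched GPCR-like class at 62/70, or a failure-pure integrin-like
  class at 0/3), optionally driving class-indicator features with no direct
  outcome dependence.

Everything is deterministic given the seed, and the marginal success
fraction of the labeled targets is exact by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from . import outcomes as oc
from .datasets import (
    CATEGORICAL,
    KINDS,
    QUANT_FILLED,
    QUANT_SPARSE,
    GeneFeatureDataset,
    write_gene_feature_tsv,
)

log = logging.getLogger(__name__)

ROW_MEAN = "row-mean"
ROW_STDV = "row-stdv"
NAMED = "named-feature"


class SimulationConfigError(ValueError):
    pass


@dataclass
class DatasetSpec:
    name: str
    kind: str = QUANT_FILLED
    n_genes: int = 600
    n_features: int = 40
    n_correlated_blocks: int = 0
    block_size: int = 5
    block_r2: float = 0.5
    global_r2: float = 0.0  # co-expression shared by *all* features
    is_human: bool = True
    # per-kind noise parameters
    loc_range: tuple[float, float] = (4.0, 10.0)  # quantitative baselines
    scale_range: tuple[float, float] = (0.5, 1.5)
    zero_fraction_range: tuple[float, float] = (0.4, 0.8)  # quantitative-sparse
    prevalence_range: tuple[float, float] = (0.05, 0.3)  # categorical-sparse


@dataclass
class PlantedEffect:
    """Outcome effect of size ``delta`` pooled SDs, applied to successes."""

    dataset: str
    role: str  # row-mean | row-stdv | named-feature
    delta: float
    sign: int = 1
    feature: str | None = None  # required for named-feature


@dataclass
class ClassSpec:
    name: str
    size: int
    success_rate: float


@dataclass
class ClassEffect:
    """Feature shifted for members of a class, independent of outcome."""

    dataset: str
    feature: str
    class_name: str
    shift: float


def default_datasets() -> list[DatasetSpec]:
    return [
        DatasetSpec(
            name="tissue-expression",
            kind=QUANT_FILLED,
            n_genes=600,
            n_features=40,
            n_correlated_blocks=4,
            block_size=5,
            block_r2=0.6,
            # real tissue atlases are heavily co-expressed: hundreds of
            # tissue features typically collapse into a handful of groups
            # around the dataset mean
            global_r2=0.5,
        ),
        DatasetSpec(
            name="pathway-membership",
            kind=CATEGORICAL,
            n_genes=500,
            n_features=60,
        ),
    ]


def default_planted_effects() -> list[PlantedEffect]:
    # successful targets: lower mean, higher dispersion of tissue expression
    return [
        PlantedEffect("tissue-expression", ROW_MEAN, delta=0.5, sign=-1),
        PlantedEffect("tissue-expression", ROW_STDV, delta=0.5, sign=+1),
    ]


def default_class_structure() -> list[ClassSpec]:
    return [
        ClassSpec("GPCR-like", size=70, success_rate=62 / 70),
        ClassSpec("integrin-like", size=3, success_rate=0.0),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_success: int = 259
    n_fail: int = 72
    n_unlabeled: int = 500
    datasets: list[DatasetSpec] = field(default_factory=default_datasets)
    planted_effects: list[PlantedEffect] = field(default_factory=default_planted_effects)
    class_structure: list[ClassSpec] = field(default_factory=default_class_structure)
    class_effects: list[ClassEffect] = field(default_factory=list)
    n_decoy_assets: int = 10


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    asset_table: list[oc.AssetRecord]
    datasets: list[GeneFeatureDataset]
    class_map: dict[str, str]
    outcome_labels: dict[str, str]
    truth: dict


def _validate(config: SimulationConfig) -> None:
    if config.n_success + config.n_fail < 6:
        raise SimulationConfigError("need at least 6 labeled targets")
    names = {d.name for d in config.datasets}
    if len(names) != len(config.datasets):
        raise SimulationConfigError("dataset names must be unique")
    kinds = {d.name: d.kind for d in config.datasets}
    for d in config.datasets:
        if d.kind not in KINDS:
            raise SimulationConfigError(f"unknown kind {d.kind!r} for {d.name}")
        if d.n_genes < config.n_success + config.n_fail:
            raise SimulationConfigError(
                f"{d.name}: n_genes must cover all labeled targets"
            )
        if d.n_correlated_blocks * d.block_size > d.n_features:
            raise SimulationConfigError(f"{d.name}: blocks exceed feature count")
    for e in config.planted_effects:
        if e.dataset not in names:
            raise SimulationConfigError(f"planted effect on unknown dataset {e.dataset}")
        if e.role not in (ROW_MEAN, ROW_STDV, NAMED):
            raise SimulationConfigError(f"unknown effect role {e.role!r}")
        if e.role == NAMED and not e.feature:
            raise SimulationConfigError("named-feature effect needs a feature label")
        if e.role in (ROW_MEAN, ROW_STDV) and kinds[e.dataset] == CATEGORICAL:
            raise SimulationConfigError(
                f"{e.role} effect undefined for categorical dataset {e.dataset}"
            )
    for ce in config.class_effects:
        if ce.dataset not in names:
            raise SimulationConfigError(f"class effect on unknown dataset {ce.dataset}")
    for cs in config.class_structure:
        if not 0.0 <= cs.success_rate <= 1.0:
            raise SimulationConfigError(f"{cs.name}: success rate outside [0, 1]")
    n_class_s = sum(round(cs.size * cs.success_rate) for cs in config.class_structure)
    n_class_f = sum(
        cs.size - round(cs.size * cs.success_rate) for cs in config.class_structure
    )
    if n_class_s > config.n_success or n_class_f > config.n_fail:
        raise SimulationConfigError("class structure exceeds labeled target counts")


def _feature_labels(n: int) -> list[str]:
    return [f"f{j:03d}" for j in range(n)]


def _pooled_sd(values: np.ndarray, y: np.ndarray) -> float:
    a, b = values[y], values[~y]
    va = a.var(ddof=1) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) if len(b) > 1 else 0.0
    dof = len(a) + len(b) - 2
    sd = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / dof) if dof > 0 else 0.0
    return float(sd) if sd > 0 else float(values.std(ddof=1))


def _latent_matrix(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal latent values with planted correlation blocks.

    Within a block each feature loads on one shared factor with loading
    a = block_r2**(1/4), giving pairwise correlation a^2 = sqrt(block_r2)
    and hence pairwise squared correlation block_r2.  ``global_r2`` adds,
    in the same parameterisation, a factor shared by *every* feature
    (emulating the broad co-expression of real tissue atlases, which is
    what makes the dataset-mean summary correlate with many features).
    """
    latent = rng.standard_normal((spec.n_genes, spec.n_features))
    if spec.global_r2 > 0:
        g = spec.global_r2**0.25
        shared = rng.standard_normal((spec.n_genes, 1))
        latent = g * shared + np.sqrt(1 - g**2) * latent
    a = spec.block_r2**0.25
    for b in range(spec.n_correlated_blocks):
        cols = slice(b * spec.block_size, (b + 1) * spec.block_size)
        factor = rng.standard_normal((spec.n_genes, 1))
        latent[:, cols] = a * factor + np.sqrt(1 - a**2) * latent[:, cols]
    return latent


def _generate_dataset(
    spec: DatasetSpec,
    genes: list[str],
    rng: np.random.Generator,
) -> GeneFeatureDataset:
    latent = _latent_matrix(spec, rng)
    n_f = spec.n_features
    if spec.kind == QUANT_FILLED:
        loc = rng.uniform(*spec.loc_range, size=n_f)
        scale = rng.uniform(*spec.scale_range, size=n_f)
        values = loc + scale * latent
    elif spec.kind == QUANT_SPARSE:
        p0 = rng.uniform(*spec.zero_fraction_range, size=n_f)
        present = latent > sps.norm.ppf(p0)  # block-correlated presence
        magnitude = rng.lognormal(mean=0.5, sigma=0.6, size=latent.shape)
        values = np.where(present, magnitude, 0.0)
    else:  # categorical-sparse
        prev = rng.uniform(*spec.prevalence_range, size=n_f)
        values = (latent > sps.norm.ppf(1 - prev)).astype(float)
    return GeneFeatureDataset(
        name=spec.name,
        kind=spec.kind,
        genes=list(genes),
        feature_labels=_feature_labels(n_f),
        values=values,
        is_human=spec.is_human,
        n_genes_total=spec.n_genes,
    )


def _apply_class_effect(
    ds: GeneFeatureDataset, effect: ClassEffect, class_map: dict[str, str]
) -> None:
    j = ds.feature_labels.index(effect.feature)
    member_rows = np.array(
        [i for i, g in enumerate(ds.genes) if class_map.get(g) == effect.class_name]
    )
    if member_rows.size == 0:
        return
    if ds.kind == CATEGORICAL:
        ds.values[member_rows, j] = 1.0 if effect.shift > 0 else 0.0
    else:
        nz = ds.values[member_rows, j] != 0 if ds.kind == QUANT_SPARSE else slice(None)
        ds.values[member_rows[nz] if ds.kind == QUANT_SPARSE else member_rows, j] += (
            effect.shift
        )


def _apply_planted_effect(
    ds: GeneFeatureDataset,
    effect: PlantedEffect,
    labeled: list[str],
    labels: dict[str, str],
) -> dict:
    """Shift the designated feature's success-failure gap by delta pooled SDs.

    Applied on the generated (pre-standardization) scale, but expressed in
    the units the downstream summary features actually carry: for the
    quantitative-filled kind the row mean and row SD are measured on the
    column-standardized view of the matrix (which is what the pipeline's
    ``mean``/``stdv`` summaries see), and the shift is mapped back through
    each column's own scale.  Row-mean shifts add a per-column constant to
    the success rows; row-SD shifts rescale each success row's deviations
    about the column means; named-feature shifts add to the named column
    (non-zero entries only for sparse kinds).
    """
    rows = ds.gene_index(labeled)
    y = np.array([labels[g] == oc.SUCCESS for g in labeled if g in set(ds.genes)])
    success_rows = rows[y]

    def gap(v: np.ndarray) -> float:  # current success - failure difference
        return float(v[y].mean() - v[~y].mean())

    if effect.role in (ROW_MEAN, ROW_STDV):
        mu = ds.values.mean(axis=0, keepdims=True)
        sd = ds.values.std(axis=0, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        z = (ds.values[rows] - mu) / sd
        if effect.role == ROW_MEAN:
            zrm = z.mean(axis=1)
            # shift relative to the realized baseline gap, so the planted
            # group-mean difference equals delta pooled SDs exactly
            shift = effect.sign * effect.delta * _pooled_sd(zrm, y) - gap(zrm)
            ds.values[success_rows] += shift * sd
        else:
            zrs = z.std(axis=1, ddof=1)
            shift = effect.sign * effect.delta * _pooled_sd(zrs, y) - gap(zrs)
            zrs_s = zrs[y]
            factor = np.maximum((zrs_s + shift) / np.where(zrs_s > 0, zrs_s, 1.0), 0.05)
            ds.values[success_rows] = mu + (ds.values[success_rows] - mu) * factor[:, None]
        realized = {"shift": float(shift)}
    else:
        j = ds.feature_labels.index(effect.feature)
        col = ds.values[rows, j]
        shift = effect.sign * effect.delta * _pooled_sd(col, y) - gap(col)
        if ds.kind in (QUANT_SPARSE, CATEGORICAL):
            nz = ds.values[success_rows, j] != 0
            ds.values[success_rows[nz], j] += shift
        else:
            ds.values[success_rows, j] += shift
        realized = {"shift": float(shift)}
    return {**asdict(effect), **realized}


def _asset_table(
    successes: list[str],
    failures: list[str],
    unlabeled: list[str],
    n_decoys: int,
    rng: np.random.Generator,
) -> list[oc.AssetRecord]:
    records: list[oc.AssetRecord] = []
    k = 0

    def rec(targets, outcome, indication="synthetic-indication", cls="other", sp="human"):
        nonlocal k
        records.append(
            oc.AssetRecord(f"A{k:05d}", tuple(targets), indication, cls, outcome, sp)
        )
        k += 1

    for t in successes:
        rec([t], "Succeeded")
        if rng.random() < 0.3:  # best-outcome-wins: successes may also have failures
            rec([t], "Failed-PhaseIII")
    for t in failures:
        rec([t], "Failed-PhaseIII")
        if rng.random() < 0.3:
            rec([t], "Failed-PhaseIII")
    for t in unlabeled[: min(20, len(unlabeled))]:
        rec([t], "InProgress-PhaseII")
    # decoys exercising every filter without touching any label
    labeled = successes + failures
    for _ in range(n_decoys):
        t = labeled[int(rng.integers(len(labeled)))]
        u = rng.random()
        if u < 0.25 and len(labeled) > 1:
            t2 = labeled[int(rng.integers(len(labeled)))]
            rec([t, t2] if t2 != t else [t, unlabeled[0] if unlabeled else t], "Succeeded")
        elif u < 0.5:
            rec([t], "Succeeded", cls="cancer")
        elif u < 0.75:
            rec([t], "Failed-PhaseII")
        else:
            rec([t], "Succeeded", sp="non-human")
    return records


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete synthetic study; deterministic given the seed."""
    _validate(config)
    rng = np.random.default_rng(config.seed)

    n_lab = config.n_success + config.n_fail
    total = n_lab + config.n_unlabeled
    ids = [f"T{i:05d}" for i in range(total)]
    successes = ids[: config.n_success]
    failures = ids[config.n_success : n_lab]
    unlabeled = ids[n_lab:]
    labels = {t: oc.SUCCESS for t in successes}
    labels.update({t: oc.FAILURE for t in failures})
    labels.update({t: oc.UNLABELED for t in unlabeled})

    # confounded target classes: exact success/failure composition
    class_map: dict[str, str] = {}
    s_pool, f_pool = list(successes), list(failures)
    rng.shuffle(s_pool)
    rng.shuffle(f_pool)
    composition = {}
    for cs in config.class_structure:
        k_s = round(cs.size * cs.success_rate)
        k_f = cs.size - k_s
        members = [s_pool.pop() for _ in range(k_s)] + [f_pool.pop() for _ in range(k_f)]
        for t in members:
            class_map[t] = cs.name
        composition[cs.name] = {"n_members": cs.size, "n_success": k_s}

    asset_table = _asset_table(
        successes, failures, unlabeled, config.n_decoy_assets, rng
    )

    datasets, truth_effects = [], []
    for spec in config.datasets:
        extra = spec.n_genes - n_lab
        others = list(unlabeled)
        rng.shuffle(others)
        genes = sorted(successes + failures + others[:extra])
        ds = _generate_dataset(spec, genes, rng)
        for ce in config.class_effects:
            if ce.dataset == spec.name:
                _apply_class_effect(ds, ce, class_map)
        labeled_in_ds = [g for g in genes if labels[g] != oc.UNLABELED]
        for pe in config.planted_effects:
            if pe.dataset == spec.name:
                truth_effects.append(_apply_planted_effect(ds, pe, labeled_in_ds, labels))
        if spec.kind == QUANT_FILLED:
            np.clip(ds.values, 0.0, None, out=ds.values)  # expression-like floor
        datasets.append(ds)

    truth = {
        "planted_effects": truth_effects,
        "class_effects": [asdict(ce) for ce in config.class_effects],
        "class_composition": composition,
        "n_success": config.n_success,
        "n_fail": config.n_fail,
    }
    return SimulatedStudy(
        config=config,
        asset_table=asset_table,
        datasets=datasets,
        class_map=class_map,
        outcome_labels=labels,
        truth=truth,
    )


def null_feature_dataset(
    n_success: int,
    n_fail: int,
    n_features: int,
    rng: np.random.Generator,
    name: str = "null",
) -> tuple[GeneFeatureDataset, dict[str, str]]:
    """A global-null Gaussian dataset over labeled targets, with its labels.

    Convenience for FDR calibration runs: equivalent to a single
    quantitative-filled dataset with no planted effects, no blocks and no
    unlabeled targets.
    """
    n = n_success + n_fail
    genes = [f"T{i:05d}" for i in range(n)]
    values = rng.standard_normal((n, n_features))
    labels = {g: (oc.SUCCESS if i < n_success else oc.FAILURE) for i, g in enumerate(genes)}
    ds = GeneFeatureDataset(
        name=name,
        kind=QUANT_FILLED,
        genes=genes,
        feature_labels=_feature_labels(n_features),
        values=values,
    )
    return ds, labels


# ---------------------------------------------------------------------------
# Study IO
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write the study as the delimited-text files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    oc.write_assets(study.asset_table, outdir / "assets.tsv")
    oc.write_class_map(study.class_map, outdir / "class_map.tsv")
    manifest = []
    for ds in study.datasets:
        fname = f"dataset_{ds.name}.tsv"
        write_gene_feature_tsv(ds, outdir / fname)
        manifest.append(
            {
                "name": ds.name,
                "kind": ds.kind,
                "file": fname,
                "is_human": ds.is_human,
                "n_genes_total": ds.n_genes_total,
            }
        )
    (outdir / "manifest.json").write_text(json.dumps({"datasets": manifest}, indent=2))
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=2))
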