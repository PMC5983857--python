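"""Calibration experiments for the screening procedure.

Self-contained simulation checks that the per-dataset screen (empirical
two-tailed permutation p-values + Benjamini-Yekutieli adjustment) controls
the false discovery rate under a global null, and that random rankings
score at chance level under the evaluation statistics.
"""

from __future__ import annotations

import numpy as np

from .dimreduce import reduce_features
from .evaluation import confusion_statistics
from .permtest import screen_dataset
from .synthetic import null_feature_dataset


def empirical_null_fdr(
    n_datasets: int = 200,
    n_success: int = 60,
    n_fail: int = 20,
    n_features: int = 50,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FDR of the screen over independent global-null datasets.

    Each dataset is pure Gaussian noise, so every rejection is false; the
    empirical FDR is the mean over datasets of
    ``false rejections / max(rejections, 1)``.  Each dataset runs the full
    screening path (redundancy reduction, shared permutation null, BY
    within dataset, rejection at adjusted p < alpha).
    """
    seeds = np.random.SeedSequence(seed).spawn(n_datasets)
    fdps = np.empty(n_datasets)
    total_rejections = 0
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        ds, labels = null_feature_dataset(n_success, n_fail, n_features, rng)
        results = screen_dataset(
            reduce_features(ds), labels, alpha=alpha, n_perm=n_perm, seed=rng
        )
        rejections = sum(r.significant for r in results)
        total_rejections += rejections
        fdps[i] = rejections / max(rejections, 1)
    return {
        "fdr": float(fdps.mean()),
        "n_datasets": n_datasets,
        "total_rejections": int(total_rejections),
    }


def random_ranking_auroc(
    n_success: int = 259,
    n_fail: int = 72,
    n_repetitions: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean AUROC/AUPR of uniformly random scores at given class sizes."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n_success + n_fail, dtype=bool)
    y[:n_success] = True
    aurocs = np.empty(n_repetitions)
    auprs = np.empty(n_repetitions)
    for i in range(n_repetitions):
        stats = confusion_statistics(y, rng.random(len(y)), threshold=0.5)
        aurocs[i] = stats["AUROC"]
        auprs[i] = stats["AUPR"]
    return {
        "mean_auroc": float(aurocs.mean()),
        "mean_aupr": float(auprs.mean()),
        "n_repetitions": n_repetitions,
    }
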