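"""Nested CV: structure, leakage guards, selection and preference rules."""

import numpy as np
import pytest

from targetscreen import outcomes as oc
from targetscreen.crossval import (
    FOREST,
    LOGISTIC,
    STRICT,
    WEAK,
    AggregatedFeatureMatrix,
    CVConfig,
    SelectedFeature,
    aggregate_features,
    fit_and_predict,
    incremental_elimination,
    outer_cv,
    univariate_select,
)
from targetscreen.datasets import QUANT_FILLED, GeneFeatureDataset
from targetscreen.dimreduce import reduce_features
from targetscreen.permtest import build_strata


def reduced_from(values, genes, name="toy", is_human=True, n_genes_total=None):
    ds = GeneFeatureDataset(
        name,
        QUANT_FILLED,
        genes,
        [f"c{j}" for j in range(values.shape[1])],
        values,
        is_human=is_human,
        n_genes_total=n_genes_total,
    )
    return reduce_features(ds)


@pytest.fixture(scope="module")
def planted_small(rng):
    n_s, n_f = 40, 16
    genes = [f"g{i}" for i in range(n_s + n_f)]
    labels = {g: (oc.SUCCESS if i < n_s else oc.FAILURE) for i, g in enumerate(genes)}
    values = np.random.default_rng(9).standard_normal((n_s + n_f, 5))
    values[:n_s, 0] += 2.0
    return reduced_from(values, genes), labels, genes


def small_cv_config(**overrides):
    base = dict(
        outer_folds=2,
        outer_reps=1,
        inner_folds=2,
        inner_reps=1,
        n_perm_univariate=300,
        min_genes=10,
        rf_n_estimators=20,
        seed=0,
    )
    base.update(overrides)
    return CVConfig(**base)


class TestUnivariateSelect:
    def test_planted_feature_selected(self, planted_small):
        red, labels, _ = planted_small
        cfg = small_cv_config()
        got = univariate_select(red, labels, None, cfg, np.random.default_rng(0))
        assert "c0" in {f.label for f in got}

    def test_weak_mode_superset_of_strict(self, planted_small):
        red, labels, _ = planted_small
        strict = univariate_select(
            red, labels, None, small_cv_config(univariate=STRICT), np.random.default_rng(1)
        )
        weak = univariate_select(
            red, labels, None, small_cv_config(univariate=WEAK), np.random.default_rng(1)
        )
        assert {f.label for f in strict} <= {f.label for f in weak}

    def test_null_dataset_strict_mostly_empty(self, rng):
        empties = 0
        for i in range(10):
            genes = [f"g{j}" for j in range(60)]
            labels = {
                g: (oc.SUCCESS if j < 45 else oc.FAILURE) for j, g in enumerate(genes)
            }
            red = reduced_from(rng.standard_normal((60, 8)), genes)
            got = univariate_select(
                red, labels, None, small_cv_config(n_perm_univariate=500),
                np.random.default_rng(i),
            )
            empties += not got
        assert empties >= 9


class TestAggregateFeatures:
    def _selected(self, name, label, p=0.001, diff=1.0):
        return {name: [SelectedFeature(name, label, p, p, diff)]}

    def test_non_human_dataset_excluded(self, rng):
        genes = [f"g{i}" for i in range(30)]
        red_h = reduced_from(rng.standard_normal((30, 2)), genes, "human_ds")
        red_m = reduced_from(rng.standard_normal((30, 2)), genes, "mouse_ds", is_human=False)
        sel = {**self._selected("human_ds", "c0"), **self._selected("mouse_ds", "c1")}
        out = aggregate_features(
            sel, {"human_ds": red_h, "mouse_ds": red_m}, genes[:20], genes,
            small_cv_config(),
        )
        assert all(l.startswith("human_ds::") for l in out.feature_labels)

    def test_small_dataset_excluded(self, rng):
        genes = [f"g{i}" for i in range(30)]
        red = reduced_from(
            rng.standard_normal((30, 2)), genes, "tiny", n_genes_total=100
        )
        out = aggregate_features(
            self._selected("tiny", "c0"), {"tiny": red}, genes[:20], genes,
            small_cv_config(min_genes=2000),
        )
        assert out is None

    def test_fallback_dataset_used_only_as_last_resort(self, rng):
        genes = [f"g{i}" for i in range(30)]
        red_a = reduced_from(rng.standard_normal((30, 2)), genes, "atlas")
        red_b = reduced_from(rng.standard_normal((30, 2)), genes, "other")
        cfg = small_cv_config(fallback_datasets=("atlas",))
        both = aggregate_features(
            {**self._selected("atlas", "c0"), **self._selected("other", "c1")},
            {"atlas": red_a, "other": red_b}, genes[:20], genes, cfg,
        )
        assert all(l.startswith("other::") for l in both.feature_labels)
        only = aggregate_features(
            self._selected("atlas", "c0"), {"atlas": red_a, "other": red_b},
            genes[:20], genes, cfg,
        )
        assert only is not None and only.feature_labels == ["atlas::c0"]

    def test_same_signal_from_two_datasets_merged(self, rng):
        genes = [f"g{i}" for i in range(40)]
        signal = rng.standard_normal(40)
        red_a = reduced_from(signal[:, None] + 0.05 * rng.standard_normal((40, 1)), genes, "a")
        red_b = reduced_from(signal[:, None] + 0.05 * rng.standard_normal((40, 1)), genes, "b")
        sel = {
            "a": [SelectedFeature("a", "c0", 0.001, 0.001, 1.0)],
            "b": [SelectedFeature("b", "c0", 0.01, 0.01, 1.0)],
        }
        out = aggregate_features(
            sel, {"a": red_a, "b": red_b}, genes[:30], genes, small_cv_config()
        )
        assert out.feature_labels == ["a::c0"]  # smaller p wins the group

    def test_training_scaling_in_unit_interval(self, rng, planted_small):
        red, labels, genes = planted_small
        sel = {"toy": [SelectedFeature("toy", "c0", 0.001, 0.001, 1.0)]}
        train = genes[:30]
        out = aggregate_features(sel, {"toy": red}, train, genes, small_cv_config())
        rows = [i for i, t in enumerate(out.targets) if t in set(train)]
        tr = out.values[rows]
        assert tr.min() >= 0 and tr.max() <= 1


class TestIncrementalElimination:
    def _matrix(self, values, genes):
        return AggregatedFeatureMatrix(
            targets=genes,
            feature_labels=[f"f{j}" for j in range(values.shape[1])],
            values=values,
            scale_min=np.zeros(values.shape[1]),
            scale_range=np.ones(values.shape[1]),
            n_dropped_targets=0,
        )

    def test_single_feature_trivial_selection(self, rng):
        genes = [f"g{i}" for i in range(40)]
        labels = {g: (oc.SUCCESS if i < 30 else oc.FAILURE) for i, g in enumerate(genes)}
        values = rng.random((40, 1))
        sel = incremental_elimination(
            self._matrix(values, genes), genes, labels, small_cv_config(),
            np.random.default_rng(0),
        )
        assert sel.selected_features == ["f0"]
        assert sel.model_type in (LOGISTIC, FOREST)

    def test_informative_feature_outlasts_nulls(self):
        kept = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(60)]
            labels = {g: (oc.SUCCESS if i < 40 else oc.FAILURE) for i, g in enumerate(genes)}
            values = r.random((60, 5))
            values[:40, 2] += 1.5  # informative
            values = (values - values.min(0)) / (values.max(0) - values.min(0))
            sel = incremental_elimination(
                self._matrix(values, genes), genes, labels,
                small_cv_config(inner_reps=2), np.random.default_rng(seed),
            )
            kept += "f2" in sel.selected_features
        assert kept >= 4

    def test_logistic_preferred_on_ties(self, rng):
        # separable single feature: both model types reach the tolerance band,
        # the preference rule must pick logistic regression
        genes = [f"g{i}" for i in range(40)]
        labels = {g: (oc.SUCCESS if i < 20 else oc.FAILURE) for i, g in enumerate(genes)}
        values = np.zeros((40, 1))
        values[:20, 0] = rng.uniform(0.7, 1.0, 20)
        values[20:, 0] = rng.uniform(0.0, 0.3, 20)
        sel = incremental_elimination(
            self._matrix(values, genes), genes, labels, small_cv_config(),
            np.random.default_rng(0),
        )
        assert sel.model_type == LOGISTIC


class TestOuterCV:
    def test_two_fold_one_rep_structure(self, planted_small):
        red, labels, genes = planted_small
        cycles = outer_cv([red], labels, {}, small_cv_config())
        assert len(cycles) == 2
        tested = sorted(t for c in cycles for t in c.test_predictions)
        assert tested == sorted(genes)  # test sets partition the labeled set

    def test_cycle_count_formula(self, planted_small):
        red, labels, _ = planted_small
        cycles = outer_cv([red], labels, {}, small_cv_config(outer_reps=3))
        assert len(cycles) == 6

    def test_no_test_target_leakage(self, planted_small):
        """Replacing test-target values with noise leaves selection unchanged."""
        red, labels, genes = planted_small
        cfg = small_cv_config()
        baseline = outer_cv([red], labels, {}, cfg)
        test_targets = set(baseline[0].test_predictions)
        import copy

        noisy = copy.deepcopy(red)
        rows = [i for i, g in enumerate(noisy.genes) if g in test_targets]
        rng2 = np.random.default_rng(99)
        for g in noisy.groups:
            g.values[rows] = rng2.standard_normal(len(rows))
        perturbed = outer_cv([noisy], labels, {}, cfg)
        b, p = baseline[0], perturbed[0]
        assert b.selection.model_type == p.selection.model_type
        assert b.selection.selected_features == p.selection.selected_features

    def test_shuffled_labels_near_chance(self, planted_small):
        from targetscreen.evaluation import repetition_stats

        red, labels, genes = planted_small
        r = np.random.default_rng(7)
        shuffled_values = list(labels.values())
        r.shuffle(shuffled_values)
        shuffled = dict(zip(labels.keys(), shuffled_values))
        cycles = outer_cv(
            [red], shuffled, {}, small_cv_config(outer_reps=4, univariate=WEAK)
        )
        scored = [c for c in cycles if not c.null_model]
        if scored:
            stats = repetition_stats(cycles, shuffled)
            med = stats.summary.loc["AUROC", "p50"]
            assert 0.25 <= med <= 0.75

    def test_probabilities_in_unit_interval_and_test_disjoint(self, planted_small):
        red, labels, _ = planted_small
        cycles = outer_cv([red], labels, {}, small_cv_config())
        for c in cycles:
            for p in c.test_predictions.values():
                assert 0.0 <= p <= 1.0

    def test_insufficient_class_counts_raise(self, rng):
        genes = [f"g{i}" for i in range(10)]
        labels = {g: (oc.SUCCESS if i < 8 else oc.FAILURE) for i, g in enumerate(genes)}
        red = reduced_from(rng.random((10, 2)), genes)
        with pytest.raises(ValueError):
            outer_cv([red], labels, {}, small_cv_config(outer_folds=5))


def test_fit_and_predict_resubstitution_bound(planted_small):
    """Refit on train=test is at least as good as held-out estimates."""
    from sklearn.metrics import roc_auc_score

    red, labels, genes = planted_small
    cfg = small_cv_config()
    sel_feats = {"toy": [SelectedFeature("toy", "c0", 0.001, 0.001, 1.0)]}
    matrix = aggregate_features(sel_feats, {"toy": red}, genes, genes, cfg)
    selection = incremental_elimination(
        matrix, genes, labels, cfg, np.random.default_rng(0)
    )
    cycle = fit_and_predict(
        selection, matrix, genes, labels, genes, [], cfg, np.random.default_rng(0)
    )
    y = np.array([labels[t] == oc.SUCCESS for t in genes])
    probs = np.array([cycle.test_predictions[t] for t in genes])
    resub = roc_auc_score(y, probs)
    inner = max(s["auroc"] for s in selection.inner_scores)
    assert resub >= inner - 0.05
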