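"""Performance panel, densities, cutoff scans and pairwise consistency."""

import numpy as np
import pandas as pd
import pytest

from targetscreen import outcomes as oc
from targetscreen.evaluation import (
    confusion_statistics,
    consistency_pair_counts,
    cutoff_scan,
    pairwise_consistency,
    probability_densities,
    repetition_stats,
    heldout_prediction_frame,
    unlabeled_prediction_frame,
)
from targetscreen.crossval import TrainTestCycle


class TestConfusionStatistics:
    def test_perfect_ranking(self):
        y = np.array([True, True, False, False])
        s = confusion_statistics(y, np.array([0.9, 0.8, 0.2, 0.1]), 0.5)
        assert s["AUROC"] == 1.0 and s["AUPR"] == 1.0

    def test_auroc_two_thirds_by_pair_counting(self):
        # 2 of 3 positive-negative score pairs concordant
        y = np.array([True, True, False, True])
        s = confusion_statistics(y, np.array([0.9, 0.8, 0.7, 0.6]), 0.5)
        assert s["AUROC"] == pytest.approx(2 / 3)

    def test_closed_form_ppv_and_mcc(self):
        # TP=3, FP=1, TN=2, FN=0
        y = np.array([True, True, True, False, False, False])
        prob = np.array([0.9, 0.8, 0.7, 0.6, 0.2, 0.1])
        s = confusion_statistics(y, prob, 0.5)
        assert (s["TP"], s["FP"], s["TN"], s["FN"]) == (3, 1, 2, 0)
        assert s["PPV"] == pytest.approx(0.75)
        mcc = (3 * 2 - 1 * 0) / np.sqrt(4 * 3 * 3 * 2)
        assert s["MCC"] == pytest.approx(mcc)
        assert s["MCC"] == pytest.approx(0.7071, abs=1e-4)

    def test_random_scores_auroc_half_aupr_prevalence(self):
        # at the historical class sizes 259/72
        rng = np.random.default_rng(2024)
        y = np.zeros(331, bool)
        y[:259] = True
        aurocs, auprs = [], []
        for _ in range(300):
            s = confusion_statistics(y, rng.random(331), 0.5)
            aurocs.append(s["AUROC"])
            auprs.append(s["AUPR"])
        se = np.std(aurocs) / np.sqrt(len(aurocs))
        assert abs(np.mean(aurocs) - 0.5) < 3 * se + 1e-3
        assert abs(np.mean(auprs) - 259 / 331) < 0.02


class TestRepetitionStats:
    def _cycles(self):
        labels = {"a": oc.SUCCESS, "b": oc.SUCCESS, "c": oc.FAILURE, "d": oc.FAILURE}
        cycles = []
        for rep, shift in enumerate((0.0, 0.05, 0.1)):
            cycles.append(
                TrainTestCycle(
                    rep=rep, fold=0, selection=None,
                    test_predictions={"a": 0.9 - shift, "b": 0.8, "c": 0.3, "d": 0.2},
                )
            )
        return cycles, labels

    def test_percentiles_monotone(self):
        cycles, labels = self._cycles()
        stats = repetition_stats(cycles, labels)
        s = stats.summary
        ok = s.notna().all(axis=1)
        assert (s.loc[ok, "p2.5"] <= s.loc[ok, "p50"] + 1e-12).all()
        assert (s.loc[ok, "p50"] <= s.loc[ok, "p97.5"] + 1e-12).all()
        assert stats.summary.loc["AUROC", "p50"] == 1.0

    def test_single_class_repetition_skipped(self):
        labels = {"a": oc.SUCCESS, "b": oc.SUCCESS}
        cycles = [
            TrainTestCycle(rep=0, fold=0, selection=None,
                           test_predictions={"a": 0.9, "b": 0.8}),
            TrainTestCycle(rep=1, fold=0, selection=None,
                           test_predictions={"a": 0.9, "b": 0.8}),
        ]
        labels["c"] = oc.FAILURE
        cycles[1].test_predictions["c"] = 0.1
        stats = repetition_stats(cycles, labels)
        assert list(stats.per_repetition.index) == [1]


class TestPredictionFrames:
    def test_unlabeled_fold_predictions_averaged(self):
        cycles = [
            TrainTestCycle(rep=0, fold=0, selection=None,
                           unlabeled_predictions={"u": 0.2}),
            TrainTestCycle(rep=0, fold=1, selection=None,
                           unlabeled_predictions={"u": 0.4}),
            TrainTestCycle(rep=1, fold=0, selection=None,
                           unlabeled_predictions={"u": 0.9}),
        ]
        frame = unlabeled_prediction_frame(cycles)
        assert frame.loc[0, "u"] == pytest.approx(0.3)
        assert frame.loc[1, "u"] == pytest.approx(0.9)

    def test_test_frame_one_value_per_rep(self):
        cycles = [
            TrainTestCycle(rep=0, fold=0, selection=None, test_predictions={"a": 0.1}),
            TrainTestCycle(rep=0, fold=1, selection=None, test_predictions={"b": 0.2}),
        ]
        frame = heldout_prediction_frame(cycles)
        assert frame.shape == (1, 2)


class TestDensities:
    def test_probability_density_integrates_to_one(self, rng):
        probs = rng.beta(2, 3, size=400)
        (d,) = probability_densities({"success": probs})
        mass = np.trapezoid(d.probability_density, d.probability_grid)
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_symmetric_logodds_symmetric_about_half(self):
        a = 1.2
        probs = 1 / (1 + np.exp(-np.array([-a, a] * 50)))
        (d,) = probability_densities({"g": probs})
        left = np.interp(0.3, d.probability_grid, d.probability_density)
        right = np.interp(0.7, d.probability_grid, d.probability_density)
        assert left == pytest.approx(right, rel=1e-6)

    def test_kde_mean_near_sample_mean(self):
        # standard-normal log-odds sample: fitted density mean within 3 SE of 0
        z = np.random.default_rng(77).standard_normal(1000)
        probs = 1 / (1 + np.exp(-z))
        (d,) = probability_densities({"g": probs})
        mean = np.trapezoid(d.logodds_grid * d.logodds_density, d.logodds_grid)
        assert abs(mean) < 3 / np.sqrt(1000)

    def test_small_group_skipped(self):
        assert probability_densities({"g": np.array([0.5, 0.6])}) == []


class TestCutoffScan:
    def test_perfect_predictions_ppv_one_smallest_cutoff(self):
        labels = {"a": oc.SUCCESS, "b": oc.SUCCESS, "c": oc.FAILURE}
        preds = pd.DataFrame(
            {"a": [0.9, 0.9], "b": [0.8, 0.8], "c": [0.1, 0.1]}
        )
        scan = cutoff_scan(preds, labels)
        assert scan.ppv_at_cutoff == 1.0
        assert scan.ppv_cutoff == 0.8  # tie toward classifying more positive
        assert scan.n_unlabeled_predicted_success == 0

    def test_random_predictions_ppv_near_base_rate(self, rng):
        n_s, n_f = 60, 20
        labels = {f"t{i}": (oc.SUCCESS if i < n_s else oc.FAILURE) for i in range(80)}
        preds = pd.DataFrame(
            rng.random((30, 80)), columns=list(labels)
        )
        scan = cutoff_scan(preds, labels)
        values = preds.to_numpy()
        # at a central cutoff the median PPV tracks the 75% base rate
        ppvs = []
        for r in range(30):
            pred = values[r] >= 0.5
            y = np.array([labels[t] == oc.SUCCESS for t in preds.columns])
            ppvs.append((pred & y).sum() / pred.sum())
        assert np.median(ppvs) == pytest.approx(0.75, abs=0.1)
        assert 0 <= scan.npv_cutoff <= 1

    def test_npv_reference_fraction(self):
        labels = {"a": oc.SUCCESS, "b": oc.FAILURE, "c": oc.FAILURE}
        preds = pd.DataFrame({"a": [0.9, 0.9], "b": [0.1, 0.1], "c": [0.2, 0.2]})
        scan = cutoff_scan(preds, labels, reference_failure_rate=0.23)
        assert scan.npv_at_cutoff == 1.0
        assert scan.npv_exceeds_reference_fraction == 1.0


class TestPairwiseConsistency:
    def test_hand_enumerated_fractions(self):
        # three targets, four repetitions, enumerate by hand
        preds = pd.DataFrame(
            {
                "A": [0.1, 0.2, 0.3, 0.4],
                "B": [0.2, 0.3, 0.2, 0.5],  # > A in reps 0,1,3 -> 3/4
                "C": [0.9, 0.8, 0.7, 0.6],  # > A and > B in all reps
            }
        )
        cm = pairwise_consistency(preds)
        i = {t: k for k, t in enumerate(cm.targets)}
        assert cm.fraction[i["A"], i["B"]] == pytest.approx(0.75)
        assert cm.fraction[i["B"], i["A"]] == pytest.approx(0.25)
        assert cm.fraction[i["A"], i["C"]] == 1.0
        assert cm.fraction[i["C"], i["A"]] == 0.0

    def test_ties_count_for_neither(self):
        preds = pd.DataFrame({"A": [0.5, 0.5], "B": [0.5, 0.5]})
        cm = pairwise_consistency(preds)
        assert cm.fraction[0, 1] == 0.0 and cm.fraction[1, 0] == 0.0

    def test_transposition_antisymmetry(self, rng):
        preds = pd.DataFrame(rng.random((10, 6)))
        cm = pairwise_consistency(preds)
        # with continuous scores frac(a,b) + frac(b,a) = 1 off-diagonal
        off = ~np.eye(6, dtype=bool)
        assert np.allclose((cm.fraction + cm.fraction.T)[off], 1.0)
        assert np.diag(cm.fraction).sum() == 0.0

    def test_pair_counts(self):
        preds = pd.DataFrame(
            {"lo": [0.1] * 10, "hi": [0.5] * 10, "mid": [0.18] * 10}
        )
        # add tiny jitter so 'hi' strictly exceeds in every repetition
        preds += np.linspace(0, 1e-6, 10)[:, None]
        cm = pairwise_consistency(preds)
        counts = consistency_pair_counts(cm)
        # lo->hi passes both rules; lo->mid only the fold-change rule fails
        # the 0.1 diff rule? |0.18-0.1|=0.08 < 0.1 but 0.18 >= 2*0.1 fails too
        assert counts.loc["median_diff", "consistency>=0.95"] == 2  # lo->hi, mid->hi
        assert counts.loc["fold_change", "consistency>=0.95"] == 2  # lo->hi, lo->mid?


class TestFeatureProjectionGrid:
    def _cycle(self, coef):
        from sklearn.linear_model import LogisticRegression
        from targetscreen.crossval import ModelSelection

        rng = np.random.default_rng(0)
        X = rng.random((60, 2))
        # labels follow the signed direction given by coef
        y = (X @ np.asarray(coef) + 0.1 * rng.standard_normal(60)) > np.median(
            X @ np.asarray(coef)
        )
        model = LogisticRegression().fit(X, y)
        return TrainTestCycle(
            rep=0,
            fold=0,
            selection=ModelSelection("logistic-regression", ["fA", "fB"], []),
            model=model,
            feature_medians=np.array([0.5, 0.5]),
        )

    def test_grid_monotone_along_weight_vector(self):
        from targetscreen.evaluation import feature_projection_grid

        cycle = self._cycle([-1.0, 1.0])  # low fA / high fB favours success
        xx, yy, grid = feature_projection_grid([cycle], ("fA", "fB"), n_grid=9)
        assert grid[-1, 0] > grid[0, -1]  # high-fB/low-fA corner wins
        assert np.all((grid >= 0) & (grid <= 1))
        # monotone down each row (increasing fA) and up each column (fB)
        assert np.all(np.diff(grid, axis=1) <= 1e-12)
        assert np.all(np.diff(grid, axis=0) >= -1e-12)

    def test_no_qualifying_cycle_gives_nan_grid(self):
        from targetscreen.evaluation import feature_projection_grid

        cycle = self._cycle([1.0, 1.0])
        _, _, grid = feature_projection_grid([cycle], ("other", "fB"), n_grid=5)
        assert np.isnan(grid).all()


def test_projection_examples_grouped_by_outcome():
    from targetscreen.crossval import AggregatedFeatureMatrix
    from targetscreen.evaluation import projection_examples

    matrix = AggregatedFeatureMatrix(
        targets=["s1", "f1", "u1"],
        feature_labels=["fA", "fB"],
        values=np.array([[0.1, 0.9], [0.8, 0.2], [0.5, 0.5]]),
        scale_min=np.zeros(2),
        scale_range=np.ones(2),
        n_dropped_targets=0,
    )
    labels = {"s1": oc.SUCCESS, "f1": oc.FAILURE, "u1": oc.UNLABELED}
    ex = projection_examples(matrix, labels, ("fA", "fB"))
    assert ex["success"].tolist() == [[0.1, 0.9]]
    assert ex["failure"].tolist() == [[0.8, 0.2]]
    assert set(ex) == {"success", "failure"}
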