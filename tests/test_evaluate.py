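"""Metric oracles, fold-assignment protocol, survival identities, embedding."""

import numpy as np
import pandas as pd
import pytest

from msfn.datatypes import LabelVector, StackedFeatures
from msfn.evaluate import (
    ConfusionCounts,
    compute_auc,
    compute_confusion_metrics,
    confusion_counts,
    embed_2d,
    km_logrank,
    metrics_row,
    run_cross_validation,
    stratified_folds,
)


class TestAUC:
    def test_four_pair_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.85])
        labels = np.array([1, 1, 0, 0])
        assert compute_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores produce ties with positive probability
            scores = np.round(rng.random(n), 1)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            expected = sum(
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            ) / (len(pos) * len(neg))
            assert compute_auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = compute_confusion_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(14 / 24)

    def test_perfect_classifier(self):
        m = compute_confusion_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert all(m[k] == 1.0 for k in m)

    def test_matches_direct_formulas(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, size=4))
            m = compute_confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            assert m["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert m["recall"] == pytest.approx(tp / (tp + fn), abs=1e-12)
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert m["f1"] == pytest.approx(2 * r * p / (r + p), abs=1e-12)
            assert m["mcc"] == pytest.approx(
                (tp * tn - fp * fn)
                / np.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)),
                abs=1e-12,
            )

    def test_zero_denominator_warns_and_reports_zero(self):
        with pytest.warns(UserWarning):
            m = compute_confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["precision"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_counts_from_predictions(self):
        cc = confusion_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == (2, 1, 1, 1)


class TestFolds:
    def test_partition_with_balanced_sizes(self):
        y = np.array([0] * 160 + [1] * 40)
        folds = stratified_folds(y, k=10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 200
        assert np.all(sizes == 20)
        # stratification: every fold holds 4 positives
        for f in range(10):
            assert y[folds == f].sum() == 4

    def test_sizes_differ_by_at_most_one(self, rng):
        y = rng.integers(0, 2, size=103)
        folds = stratified_folds(y, k=10, seed=3)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1

    def test_no_patient_in_two_test_folds(self, rng):
        y = rng.integers(0, 2, size=57)
        folds = stratified_folds(y, k=5, seed=1)
        assert folds.min() >= 0 and folds.max() < 5
        assert len(folds) == 57  # each patient has exactly one fold id

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.zeros(10), k=1)


def test_run_cross_validation_averages_per_fold(rng):
    """Metrics are computed per fold then averaged, never pooled."""
    n = 100
    y = rng.integers(0, 2, size=n)
    ids = np.array([f"P{i}" for i in range(n)], dtype=object)
    labels = LabelVector(ids, y)
    truth = rng.random(n)  # fixed scores independent of the fold

    def fit_predict(views, labels_, train_mask, fold_seed):
        scores = np.where(labels_.label == 1, 0.4 + truth * 0.6, truth * 0.6)
        return scores, (scores >= 0.5).astype(int)

    report = run_cross_validation({}, labels, fit_predict, k=5, seed=0)
    assert len(report.per_fold) == 5
    folds = stratified_folds(y, k=5, seed=0)
    expected_auc = np.mean(
        [
            metrics_row(
                y[folds == f],
                fit_predict(None, labels, None, 0)[0][folds == f],
                fit_predict(None, labels, None, 0)[1][folds == f],
            )["auc"]
            for f in range(5)
        ]
    )
    assert report.mean["auc"] == pytest.approx(expected_auc)
    assert report.mean["auc"] == pytest.approx(report.per_fold["auc"].mean())


class TestSurvival:
    def test_identical_groups_give_null_statistic(self):
        times = np.array([5.0, 10, 20, 30, 40, 5, 10, 20, 30, 40])
        events = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
        groups = np.array([0] * 5 + [1] * 5)
        curves, stat, p = km_logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_extreme_separation_is_significant(self):
        times = np.array([1.0] * 12 + [10.0] * 12)
        events = np.array([1] * 12 + [0] * 12)
        groups = np.array([0] * 12 + [1] * 12)
        _, stat, p = km_logrank(times, events, groups)
        assert p < 0.01

    def test_curves_start_at_one_and_decrease(self, rng):
        times = rng.exponential(20, size=40) + 0.1
        events = rng.integers(0, 2, size=40)
        groups = (np.arange(40) % 2).astype(int)
        curves, _, _ = km_logrank(times, events, groups)
        for curve in curves.values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == pytest.approx(1.0)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], [0, 0])


class TestEmbedding:
    def _stacked(self, rng, n=40):
        y = (np.arange(n) % 2).astype(int)
        X = rng.standard_normal((n, 8)) + 10.0 * y[:, None]
        ids = np.array([f"P{i}" for i in range(n)], dtype=object)
        return StackedFeatures(values=X, patient_ids=ids), y

    def test_shape_and_determinism(self, rng):
        stacked, y = self._stacked(rng)
        a = embed_2d(stacked, y, seed=0)
        b = embed_2d(stacked, y, seed=0)
        assert a.shape == (40, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        stacked, y = self._stacked(rng, n=60)
        coords = embed_2d(stacked, y, seed=1)
        assert silhouette_score(coords, y) > 0.5

    def test_plot_written(self, rng, tmp_path):
        stacked, y = self._stacked(rng)
        path = tmp_path / "tsne.png"
        embed_2d(stacked, y, seed=0, path=str(path))
        assert path.exists() and path.stat().st_size > 0

    def test_too_few_patients_rejected(self, rng):
        stacked, y = self._stacked(rng, n=8)
        with pytest.raises(ValueError):
            embed_2d(stacked, y, seed=0)
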