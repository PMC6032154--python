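"""Confusion metrics, ROC/AUC, cross-validation and jackknife protocols."""

import itertools

import numpy as np
import pytest

from ggapnb import (
    ConfusionCounts,
    PipelineConfig,
    encode,
    jackknife,
    kfold_cv,
    metrics,
    roc_auc,
)
from ggapnb.errors import InvalidArgumentError


def concordance_auc(scores, labels):
    """Oracle: Mann-Whitney pairwise concordance with ties counting 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_prediction(self):
        r = metrics(ConfusionCounts(tp=99, tn=208, fp=0, fn=0))
        assert (r.sn, r.sp, r.acc, r.mcc) == (100.0, 100.0, 100.0, 100.0)

    def test_benchmark_scale_confusion_matrix(self):
        # 99 positives / 208 negatives with 3 + 2 errors
        r = metrics(ConfusionCounts(tp=96, tn=206, fp=2, fn=3))
        assert round(r.sn, 2) == 96.97
        assert round(r.sp, 2) == 99.04
        assert round(r.acc, 2) == 98.37
        assert round(r.mcc, 2) == 96.27

    def test_random_prediction_has_zero_mcc(self):
        r = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert r.mcc == pytest.approx(0.0)
        assert r.acc == pytest.approx(50.0)

    def test_zero_marginal_mcc_defined_as_zero(self):
        r = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert r.mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConfusionCounts(0, 0, 0, 0)
        with pytest.raises(InvalidArgumentError):
            ConfusionCounts(-1, 1, 0, 0)

    def test_accuracy_is_class_size_weighted_sn_sp(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            tp, tn, fp, fn = rng.integers(1, 40, size=4)
            r = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            n_pos, n_neg = tp + fn, tn + fp
            weighted = (r.sn * n_pos + r.sp * n_neg) / (n_pos + n_neg)
            assert r.acc == pytest.approx(weighted, abs=1e-9)

    def test_mcc_symmetric_under_class_swap(self):
        r1 = metrics(ConfusionCounts(tp=8, tn=3, fp=4, fn=1))
        r2 = metrics(ConfusionCounts(tp=3, tn=8, fp=1, fn=4))
        assert r1.mcc == pytest.approx(r2.mcc, abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        *_, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_tied_scores(self):
        *_, auc = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_hand_counted_concordance(self):
        # positives 0.9, 0.4 vs negatives 0.35, 0.8: 3 of 4 pairs concordant
        *_, auc = roc_auc([0.9, 0.4, 0.35, 0.8], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_trapezoid_equals_pairwise_concordance(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(4, 21))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            # quantized scores force ties through the sweep
            scores = np.round(rng.random(n), 1)
            *_, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_auc([0.1, 0.9], [1, 1])


@pytest.fixture(scope="module")
def planted_matrix(planted_dataset, small_vocab):
    m = encode(planted_dataset.records, small_vocab)
    return m, planted_dataset.labels


class TestCrossValidation:
    def test_same_seed_reproduces_folds_and_metrics(self, planted_matrix):
        m, labels = planted_matrix
        config = PipelineConfig(n_features=50)
        r1 = kfold_cv(m, labels, config, k=5, seed=3)
        r2 = kfold_cv(m, labels, config, k=5, seed=3)
        assert (r1.counts, r1.auc) == (r2.counts, r2.auc)

    def test_pooled_counts_sum_to_n(self, planted_matrix):
        m, labels = planted_matrix
        r = kfold_cv(m, labels, PipelineConfig(n_features=50), k=5, seed=0)
        assert r.counts.total == len(labels)
        assert sum(c.total for c in r.fold_counts) == len(labels)

    def test_separable_data_scores_high(self, planted_matrix):
        m, labels = planted_matrix
        r = kfold_cv(m, labels, PipelineConfig(n_features=50), k=5, seed=0)
        assert r.acc > 95.0
        assert r.auc > 0.95

    def test_class_smaller_than_k_rejected(self, planted_matrix):
        m, _ = planted_matrix
        labels = np.array([1] * 3 + [0] * (m.n_samples - 3))
        with pytest.raises(InvalidArgumentError):
            kfold_cv(m, labels, PipelineConfig(n_features=10), k=5, seed=0)

    def test_global_leakage_policy_runs(self, planted_matrix):
        m, labels = planted_matrix
        config = PipelineConfig(n_features=50, leakage="global")
        r = kfold_cv(m, labels, config, k=5, seed=0)
        assert r.counts.total == len(labels)


@pytest.fixture(scope="module")
def toy():
    # columns 0/1 are complementary exact class indicators
    labels = np.array([1, 0, 1, 0, 1, 0, 1, 0, 0])
    values = np.zeros((9, 4))
    values[labels == 1, 0] = 0.9
    values[labels == 0, 1] = 0.9
    rng = np.random.default_rng(21)
    values[:, 2:] = rng.random((9, 2)) * 0.05
    return values, labels


class TestJackknife:
    def test_separable_toy_is_perfect(self, toy):
        values, labels = toy
        r = jackknife(values, labels, PipelineConfig(n_features=2))
        assert r.acc == 100.0

    def test_equals_kfold_with_k_equal_n(self, toy):
        values, labels = toy
        config = PipelineConfig(n_features=2)
        r1 = jackknife(values, labels, config)
        r2 = kfold_cv(values, labels, config, k=len(labels))
        assert r1.counts == r2.counts

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            jackknife(np.ones((2, 2)), np.array([0, 1]), PipelineConfig())
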