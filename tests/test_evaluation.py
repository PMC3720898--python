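import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgxlearn as pg
from pgxlearn.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    accuracy,
    compute_metric,
    f_score,
    kfold_partitions,
    multiclass_auc,
    precision,
    recall,
    rmse,
    roc_auc,
)
from pgxlearn.labeling import LabelSet
from pgxlearn.models import ModelSpec


def brute_force_auc(scores, labels, positive):
    """Pair-counting oracle: P(positive outscores negative), ties half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_hand_till(prob, labels, classes):
    """Average over unordered class pairs of ½[A(i|j) + A(j|i)]."""
    total, pairs = 0.0, 0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            keep = [i for i, l in enumerate(labels) if l in (classes[a], classes[b])]
            sub_labels = [labels[i] for i in keep]
            a_given_b = brute_force_auc([prob[i][a] for i in keep], sub_labels, classes[a])
            b_given_a = brute_force_auc([prob[i][b] for i in keep], sub_labels, classes[b])
            total += 0.5 * (a_given_b + b_given_a)
            pairs += 1
    return total / pairs


class TestRmse:
    def test_identical_is_zero(self, rng):
        v = rng.standard_normal(10)
        assert rmse(v, v) == 0.0

    def test_worked_example(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(3.53553, abs=1e-5)

    def test_translation_invariance(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        assert rmse(a + 2.5, b + 2.5) == pytest.approx(rmse(a, b))

    def test_triangle_bound(self, rng):
        a, b, c = rng.standard_normal((3, 12))
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1], [1, 2])
        with pytest.raises(ValueError):
            rmse([], [])


class TestConfusionMetrics:
    def test_worked_example(self):
        cc = ConfusionCounts(tp=8, fp=2, tn=6, fn=4)
        assert precision(cc) == pytest.approx(0.8)
        assert recall(cc) == pytest.approx(0.66667, abs=1e-5)
        assert f_score(cc) == pytest.approx(0.72727, abs=1e-5)
        assert accuracy(cc) == pytest.approx(0.7)

    def test_f1_equals_rate_when_precision_equals_recall(self):
        cc = ConfusionCounts(tp=6, fp=2, tn=5, fn=2)
        assert precision(cc) == recall(cc) == f_score(cc)

    def test_perfect_classifier(self):
        cc = ConfusionCounts(tp=5, fp=0, tn=5, fn=0)
        assert precision(cc) == recall(cc) == f_score(cc) == 1.0

    def test_zero_denominator_signaled(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(tp=0, fp=5, tn=5, fn=0))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.9, 0.4, 0.8, 0.3], [2, 2, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [2, 2, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 6, [2, 2, 2, 1, 1, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        labels = rng.choice([1, 2], size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 1, 2
        scores = np.round(rng.uniform(0, 1, size=n), 1)  # rounding forces ties
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels, positive=2), abs=1e-12
        )


class TestMulticlassAuc:
    def test_two_class_reduction(self, rng):
        labels = np.array([1, 2, 1, 2, 1, 2])
        p2 = rng.uniform(0, 1, 6)
        prob = np.column_stack([1 - p2, p2])
        assert multiclass_auc(prob, labels) == pytest.approx(roc_auc(p2, labels))

    def test_perfectly_ordered_probabilities(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        prob = np.array([
            [0.8, 0.1, 0.1], [0.7, 0.2, 0.1],
            [0.1, 0.8, 0.1], [0.2, 0.7, 0.1],
            [0.1, 0.1, 0.8], [0.1, 0.2, 0.7],
        ])
        assert multiclass_auc(prob, labels) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        labels = np.concatenate([[1, 2, 3], rng.choice([1, 2, 3], size=n - 3)])
        prob = rng.dirichlet(np.ones(3), size=n)
        expected = brute_force_hand_till(prob, labels, [1, 2, 3])
        assert multiclass_auc(prob, labels) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_class_relabeling(self, rng):
        labels = np.concatenate([[1, 2, 3], rng.choice([1, 2, 3], size=9)])
        prob = rng.dirichlet(np.ones(3), size=12)
        base = multiclass_auc(prob, labels)
        # swap classes 1 and 3 (and the matching probability columns)
        relabeled = np.select([labels == 1, labels == 2, labels == 3], [3, 2, 1])
        assert multiclass_auc(prob[:, ::-1], relabeled) == pytest.approx(base)

    def test_missing_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            multiclass_auc(np.ones((3, 1)), np.array([1, 1, 1]))


class TestKfoldPartitions:
    def test_even_split(self):
        folds = kfold_partitions(100, 10, seed=0)
        assert [len(f) for f in folds] == [10] * 10

    def test_remainder_distribution(self):
        folds = kfold_partitions(22, 10, seed=0)
        assert sorted((len(f) for f in folds), reverse=True) == [3, 3, 2, 2, 2, 2, 2, 2, 2, 2]

    def test_disjoint_union(self):
        folds = kfold_partitions(37, 5, seed=3)
        combined = np.concatenate(folds)
        assert len(combined) == 37 and len(np.unique(combined)) == 37

    def test_seed_determinism(self):
        a = kfold_partitions(30, 4, seed=9)
        b = kfold_partitions(30, 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_partitions(5, 10, seed=0)


class TestCrossValidate:
    def test_noiseless_linear_recovery(self, fast_hp):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 10))
        y = LabelSet("regression", 2.0 * X[:, 0])
        res = pg.cross_validate(
            ModelSpec("elastic_net", "regression", fast_hp), X, y, k=10, repeats=1, seed=0
        )
        assert res.metric_name == "RMSE"
        assert res.per_repeat[0] < 0.1

    def test_per_repeat_length_matches_repeats(self, fast_hp):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 8))
        y = LabelSet("regression", X[:, 0] + 0.1 * rng.standard_normal(30))
        res = pg.cross_validate(
            ModelSpec("elastic_net", "regression", fast_hp), X, y, k=5, repeats=10, seed=2
        )
        assert len(res.per_repeat) == 10
        assert np.isfinite(res.per_repeat).all()
        assert res.median == pytest.approx(np.median(res.per_repeat))

    def test_determinism(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        spec = ModelSpec("rf", "binary", fast_hp)
        a = pg.cross_validate(spec, X, labels["binary"], k=5, repeats=2, seed=7)
        b = pg.cross_validate(spec, X, labels["binary"], k=5, repeats=2, seed=7)
        np.testing.assert_array_equal(a.per_repeat, b.per_repeat)


def test_compute_metric_requires_proba_for_auc():
    with pytest.raises(ValueError):
        compute_metric("AUC", [1, 2], [1, 2])
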