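import numpy as np
import pytest

from pgxlearn.evaluation import kfold_partitions, single_cv_predictions
from pgxlearn.labeling import LabelSet
from pgxlearn.models import (
    ALGORITHMS,
    DegenerateFoldError,
    ModelSpec,
    allowed_combinations,
    fit,
    tune_svm_nested,
)

DASH_CELLS = [
    ("elastic_net", "binary"),
    ("elastic_net", "class3"),
    ("l1_logistic", "regression"),
    ("l1_logistic", "class3"),
]


class TestCombinationTable:
    def test_seventeen_valid_cells(self):
        assert len(allowed_combinations()) == 17

    def test_elastic_net_regression_only(self):
        combos = allowed_combinations()
        assert ("elastic_net", "regression", "RMSE") in combos
        assert not any(a == "elastic_net" and l != "regression" for a, l, _ in combos)

    def test_metric_assignments(self):
        metric = {(a, l): m for a, l, m in allowed_combinations()}
        assert metric[("svm", "class3")] == "F1"
        assert metric[("svm", "binary")] == "Accuracy"
        assert metric[("rf", "binary")] == "AUC"
        assert metric[("rf", "class3")] == "mAUC"
        assert metric[("l1_logistic", "binary")] == "AUC"
        assert all(m == "RMSE" for (a, l), m in metric.items() if l == "regression")

    @pytest.mark.parametrize("algo,labeling", DASH_CELLS)
    def test_dash_cells_unconstructible(self, algo, labeling):
        with pytest.raises(ValueError):
            ModelSpec(algo, labeling)

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("rf", "binary", {"bogus": 1})


class TestFitAcrossTable:
    def test_all_seventeen_cells_fit_and_predict(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        for algo, labeling, metric in allowed_combinations():
            model = fit(ModelSpec(algo, labeling, fast_hp), X, labels[labeling], seed=0)
            pred = model.predict(X[:4])
            assert pred.shape == (4,)
            if labels[labeling].is_classification:
                assert set(np.asarray(pred, dtype=int)) <= set(np.unique(labels[labeling].values))

    def test_labeling_mismatch_rejected(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        with pytest.raises(ValueError):
            fit(ModelSpec("rf", "binary", fast_hp), X, labels["regression"], seed=0)

    def test_single_class_fold_rejected(self, fast_hp, rng):
        X = rng.standard_normal((10, 5))
        y = LabelSet("binary", np.ones(10, dtype=int))
        with pytest.raises(DegenerateFoldError):
            fit(ModelSpec("rf", "binary", fast_hp), X, y, seed=0)


class TestCompositeRecords:
    def test_two_stage_selects_top_300_when_p_larger(self, fast_hp, rng):
        X = rng.standard_normal((40, 400))
        y = LabelSet("regression", X[:, 0] + 0.5 * rng.standard_normal(40))
        model = fit(ModelSpec("two_stage_rf", "regression", fast_hp), X, y, seed=0)
        assert model.selected_features.shape == (300,)
        assert len(np.unique(model.selected_features)) == 300

    def test_two_stage_uses_all_genes_when_p_small(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]  # p = 120 < 300
        model = fit(ModelSpec("two_stage_rf", "binary", fast_hp), X, labels["binary"], seed=0)
        assert model.selected_features.shape == (X.shape[1],)

    def test_two_stage_regression_ranking_finds_signal_genes(self, fast_hp, rng):
        # y depends only on genes 0..4; a 10-gene screen must find them
        X = rng.standard_normal((100, 50))
        y = LabelSet("regression", X[:, :5].sum(axis=1))
        hp = dict(fast_hp, top_genes=10, n_trees=300)
        model = fit(ModelSpec("two_stage_rf", "regression", hp), X, y, seed=0)
        assert len(set(model.selected_features) & set(range(5))) >= 4

    @pytest.mark.parametrize("algo", ["pca_rf", "pca_svm"])
    def test_pca_exposes_five_components(self, algo, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        model = fit(ModelSpec(algo, "regression", fast_hp), X, labels["regression"], seed=0)
        assert model.components.shape == (5, X.shape[1])

    def test_rf_probabilities_sum_to_one(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        model = fit(ModelSpec("rf", "class3", fast_hp), X, labels["class3"], seed=0)
        proba = model.predict_proba(X[:10])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_svm_has_no_probabilities(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        model = fit(ModelSpec("svm", "binary", fast_hp), X, labels["binary"], seed=0)
        with pytest.raises(AttributeError):
            model.predict_proba(X[:2])

    def test_feature_count_mismatch_rejected(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        model = fit(ModelSpec("rf", "regression", fast_hp), X, labels["regression"], seed=0)
        with pytest.raises(ValueError):
            model.predict(X[:, :10])


class TestFitQuality:
    def test_elastic_net_recovers_noiseless_signal(self, fast_hp, rng):
        X = rng.standard_normal((50, 10))
        y = LabelSet("regression", 2.0 * X[:, 0])
        model = fit(ModelSpec("elastic_net", "regression", fast_hp), X, y, seed=0)
        train_rmse = float(np.sqrt(np.mean((model.predict(X) - y.values) ** 2)))
        assert train_rmse < 0.1

    def test_svm_separates_distant_blobs(self, fast_hp, rng):
        X = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(10, 1, (20, 5))])
        y = LabelSet("binary", np.repeat([1, 2], 20))
        model = fit(ModelSpec("svm", "binary", fast_hp), X, y, seed=0)
        assert np.mean(model.predict(X) == y.values) == 1.0

    def test_rf_regression_fits_training_data(self, fast_hp, small_panel_xy):
        X, labels = small_panel_xy["state1"]
        y = labels["regression"]
        model = fit(ModelSpec("rf", "regression", fast_hp), X, y, seed=0)
        in_bag_rmse = float(np.sqrt(np.mean((model.predict(X) - y.values) ** 2)))
        assert in_bag_rmse < np.std(y.values) / 2


class TestSvmTuning:
    def test_grid_of_one_returned_directly(self, rng):
        X = rng.standard_normal((20, 4))
        y = LabelSet("regression", X[:, 0])
        grid = [{"C": 1.0, "gamma": 0.25, "epsilon": 0.1}]
        assert tune_svm_nested(X, y, grid, inner_k=3, seed=0) == grid[0]

    def test_small_epsilon_wins_on_noiseless_data(self, rng):
        X = rng.standard_normal((40, 4))
        y = LabelSet("regression", X[:, 0])
        grid = [
            {"C": 10.0, "gamma": 0.25, "epsilon": 0.01},
            {"C": 10.0, "gamma": 0.25, "epsilon": 10.0},
        ]
        chosen = tune_svm_nested(X, y, grid, inner_k=5, seed=0)
        assert chosen["epsilon"] == 0.01

    def test_seeded_choice_is_deterministic(self, rng):
        X = rng.standard_normal((30, 4))
        y = LabelSet("binary", (X[:, 0] > 0).astype(int) + 1)
        grid = [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in (0.1, 0.5)]
        a = tune_svm_nested(X, y, grid, inner_k=3, seed=4)
        b = tune_svm_nested(X, y, grid, inner_k=3, seed=4)
        assert a == b

    def test_empty_grid_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = LabelSet("regression", X[:, 0])
        with pytest.raises(ValueError):
            tune_svm_nested(X, y, [], inner_k=3, seed=0)


class TestLeakageGuard:
    @pytest.mark.parametrize("algo,labeling", [("pca_rf", "regression"), ("two_stage_rf", "binary")])
    def test_test_fold_perturbation_leaves_fold_models_unchanged(
        self, algo, labeling, fast_hp, small_panel_xy
    ):
        """Held-out rows must not influence in-fold PCA / gene selection."""
        X, labels = small_panel_xy["state1"]
        y = labels[labeling]
        hp = dict(fast_hp, top_genes=30)
        spec = ModelSpec(algo, labeling, hp)
        folds = kfold_partitions(X.shape[0], 5, seed=11)
        _, _, base_models = single_cv_predictions(spec, X, y, folds, seed=11)
        rng = np.random.default_rng(99)
        for f_idx in range(2):  # perturb two different test folds
            X_poisoned = X.copy()
            X_poisoned[folds[f_idx]] = rng.standard_normal((len(folds[f_idx]), X.shape[1]))
            _, _, new_models = single_cv_predictions(spec, X_poisoned, y, folds, seed=11)
            if algo == "pca_rf":
                np.testing.assert_array_equal(
                    base_models[f_idx].components, new_models[f_idx].components
                )
            else:
                np.testing.assert_array_equal(
                    base_models[f_idx].selected_features, new_models[f_idx].selected_features
                )
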