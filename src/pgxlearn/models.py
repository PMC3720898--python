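"""The seven learner configurations behind a single fit/predict contract.

Each algorithm is valid for a subset of the three labelings and is scored by
one metric (the non-dash cells of the study design's algorithm × labeling
table — 17 valid combinations in total):

====================  ==========  ========  ======
algorithm             regression  binary    class3
====================  ==========  ========  ======
elastic_net           RMSE        —         —
l1_logistic           —           AUC       —
pca_rf                RMSE        AUC       mAUC
pca_svm               RMSE        Accuracy  F1
svm                   RMSE        Accuracy  F1
rf                    RMSE        AUC       mAUC
two_stage_rf          RMSE        AUC       mAUC
====================  ==========  ========  ======

Conventions follow the common R-ecosystem defaults for this problem class:
elastic net with mixing parameter α = 0.5 and internally cross-validated
penalty strength; L1 logistic regression (selects at most n features);
RBF-kernel SVMs with reciprocal-class-size weights and hyperparameters chosen
by nested cross-validation; random forests with 500 trees, √p split
candidates for classification and p/3 for regression, class probabilities
from normalized tree votes. The two composite procedures run entirely inside
each training fold: ``pca_*`` projects onto the first five principal
components before the base learner, and ``two_stage_rf`` ranks genes with a
first forest (Gini importance for classification, out-of-bag permutation MSE
increase for regression), keeps the top 300, and refits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LogisticRegressionCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor

from ._util import derive_seed
from .evaluation import compute_metric, kfold_partitions, metric_direction
from .labeling import LABELING_KINDS, LabelSet

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "FittedModel",
    "DegenerateFoldError",
    "allowed_combinations",
    "metric_for",
    "default_hyperparams",
    "fit",
    "tune_svm_nested",
]

ALGORITHMS = ("elastic_net", "l1_logistic", "pca_rf", "pca_svm", "svm", "rf", "two_stage_rf")

# Non-dash cells of the algorithm × labeling table, with the reported metric.
_TABLE: dict[tuple[str, str], str] = {
    ("elastic_net", "regression"): "RMSE",
    ("l1_logistic", "binary"): "AUC",
    ("pca_rf", "regression"): "RMSE",
    ("pca_rf", "binary"): "AUC",
    ("pca_rf", "class3"): "mAUC",
    ("pca_svm", "regression"): "RMSE",
    ("pca_svm", "binary"): "Accuracy",
    ("pca_svm", "class3"): "F1",
    ("svm", "regression"): "RMSE",
    ("svm", "binary"): "Accuracy",
    ("svm", "class3"): "F1",
    ("rf", "regression"): "RMSE",
    ("rf", "binary"): "AUC",
    ("rf", "class3"): "mAUC",
    ("two_stage_rf", "regression"): "RMSE",
    ("two_stage_rf", "binary"): "AUC",
    ("two_stage_rf", "class3"): "mAUC",
}

_PROBABILITY_ALGOS = {"l1_logistic", "rf", "two_stage_rf", "pca_rf"}


class DegenerateFoldError(ValueError):
    """Training data cannot support the requested model (e.g. a class with <2 samples)."""


def allowed_combinations() -> list[tuple[str, str, str]]:
    """All 17 valid (algorithm, labeling_kind, metric) cells, in table order."""
    out = []
    for algo in ALGORITHMS:
        for kind in LABELING_KINDS:
            if (algo, kind) in _TABLE:
                out.append((algo, kind, _TABLE[(algo, kind)]))
    return out


def default_hyperparams() -> dict[str, Any]:
    return {
        "n_trees": 500,
        "pca_components": 5,
        "top_genes": 300,
        "enet_cv": 5,
        "enet_alphas": 100,
        "logistic_Cs": 10,
        "logistic_cv": 5,
        "svm_inner_k": 5,
        "svm_C": (0.01, 0.1, 1.0, 10.0, 100.0),
        "svm_gamma_scale": (0.1, 1.0, 10.0),  # multiples of 1/p
        "svm_epsilon": (0.01, 0.1, 1.0),
        "svm_kernel": "rbf",
    }


@dataclass(frozen=True)
class ModelSpec:
    """One algorithm + labeling + hyperparameter overrides.

    Only the non-dash table cells are constructible; anything else raises at
    creation time.
    """

    algorithm: str
    labeling_kind: str
    hyperparams: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.labeling_kind not in LABELING_KINDS:
            raise ValueError(f"unknown labeling {self.labeling_kind!r}")
        if (self.algorithm, self.labeling_kind) not in _TABLE:
            raise ValueError(
                f"({self.algorithm}, {self.labeling_kind}) is not a valid "
                "algorithm/labeling combination"
            )
        unknown = set(self.hyperparams) - set(default_hyperparams())
        if unknown:
            raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")

    @property
    def metric_name(self) -> str:
        return _TABLE[(self.algorithm, self.labeling_kind)]

    def resolved(self) -> dict[str, Any]:
        hp = default_hyperparams()
        hp.update(self.hyperparams)
        return hp


def metric_for(spec: ModelSpec) -> str:
    return spec.metric_name


@dataclass
class FittedModel:
    """Opaque fitted state plus the records the composite procedures expose."""

    spec: ModelSpec
    estimator: Any
    classes_: np.ndarray | None = None
    components: np.ndarray | None = None  # pca_*: the fitted projection (k × p)
    pca_: Any = None
    selected_features: np.ndarray | None = None  # two_stage_rf: retained gene indices
    chosen_params: dict[str, Any] | None = None  # svm: nested-CV winners
    n_features_in_: int = 0

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
            )
        if self.pca_ is not None:
            return self.pca_.transform(X)
        if self.selected_features is not None:
            return X[:, self.selected_features]
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._transform(X)))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probabilities (columns follow ``classes_``); unavailable for SVMs."""
        if self.spec.algorithm in ("svm", "pca_svm"):
            raise AttributeError("SVMs do not provide class probabilities")
        return np.asarray(self.estimator.predict_proba(self._transform(X)))


def _check_classification(y: LabelSet) -> np.ndarray:
    classes, counts = np.unique(y.values, return_counts=True)
    if len(classes) < 2:
        raise DegenerateFoldError("training fold contains a single class")
    if counts.min() < 2:
        raise DegenerateFoldError("a class has fewer than 2 training samples")
    return classes


def _reciprocal_class_weights(y: np.ndarray) -> dict[int, float]:
    classes, counts = np.unique(y, return_counts=True)
    return {int(c): 1.0 / int(m) for c, m in zip(classes, counts)}


def _rf_mtry(p: int, classification: bool) -> int:
    return max(1, int(math.sqrt(p)) if classification else p // 3)


def _make_rf(p: int, y: LabelSet, n_trees: int, seed: int):
    if y.is_classification:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_features=_rf_mtry(p, True),
            random_state=seed,
            n_jobs=1,
        )
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=_rf_mtry(p, False),
        random_state=seed,
        n_jobs=1,
    )


def _svm_grid(p: int, hp: Mapping[str, Any], regression: bool) -> list[dict[str, float]]:
    grid = []
    for C in hp["svm_C"]:
        for gs in hp["svm_gamma_scale"]:
            gamma = gs / p
            if regression:
                for eps in hp["svm_epsilon"]:
                    grid.append({"C": float(C), "gamma": float(gamma), "epsilon": float(eps)})
            else:
                grid.append({"C": float(C), "gamma": float(gamma)})
    return grid


def _make_svm(params: Mapping[str, float], y: LabelSet, kernel: str):
    # features are standardized inside the estimator (the convention of the
    # LIBSVM wrappers this design follows), so the 1/p-scaled gamma grid is
    # meaningful regardless of the input scale
    if y.is_classification:
        svm = SVC(
            C=params["C"],
            gamma=params["gamma"],
            kernel=kernel,
            class_weight=_reciprocal_class_weights(y.values),
        )
    else:
        svm = SVR(C=params["C"], gamma=params["gamma"], epsilon=params["epsilon"], kernel=kernel)
    return make_pipeline(StandardScaler(), svm)


def tune_svm_nested(
    X: np.ndarray,
    y: LabelSet,
    grid: Sequence[Mapping[str, float]],
    inner_k: int,
    seed: int,
    kernel: str = "rbf",
) -> dict[str, float]:
    """Choose SVM hyperparameters by an inner cross-validation on (X, y).

    The inner-CV metric is the one the outer evaluation reports for SVMs
    (RMSE / accuracy / macro-F1 depending on the labeling). Ties break toward
    simpler models: smaller C, then larger ε, then smaller γ.
    """
    if len(grid) == 0:
        raise ValueError("empty tuning grid")
    grid = sorted(grid, key=lambda g: (g["C"], -g.get("epsilon", 0.0), g["gamma"]))
    if len(grid) == 1:
        return dict(grid[0])
    metric = "RMSE" if not y.is_classification else ("Accuracy" if y.labeling_kind == "binary" else "F1")
    sign = -1.0 if metric_direction(metric) == "lower_better" else 1.0
    n = X.shape[0]
    folds = kfold_partitions(n, min(inner_k, n), derive_seed(seed, 7))
    best_params, best_score = None, -np.inf
    for params in grid:
        y_pred = np.empty(n, dtype=float)
        try:
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                y_train = LabelSet(y.labeling_kind, y.values[train_idx], y.thresholds)
                if y.is_classification and len(np.unique(y_train.values)) < 2:
                    raise DegenerateFoldError("single-class inner fold")
                est = _make_svm(params, y_train, kernel)
                est.fit(X[train_idx], y_train.values)
                y_pred[test_idx] = est.predict(X[test_idx])
        except DegenerateFoldError:
            continue
        score = sign * compute_metric(metric, y.values, y_pred)
        if score > best_score:  # strict: earlier (simpler) grid points win ties
            best_params, best_score = params, score
    if best_params is None:
        best_params = grid[0]
    return dict(best_params)


def _oob_permutation_importance_regression(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    """Mean OOB MSE increase per feature for a hand-bagged regression forest.

    Equivalent to the classical unscaled %IncMSE: for each tree, out-of-bag
    samples are re-predicted with one feature column permuted and the MSE
    increase is attributed to that feature (features unused by a tree
    contribute zero). Permutations are batched per tree, restricted to the
    features its splits actually use, which keeps the computation tractable
    at microarray dimensions.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    mtry = _rf_mtry(p, classification=False)
    increase = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if len(oob) == 0:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base_mse = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if len(used) == 0:
            continue
        batch = np.repeat(X_oob[None, :, :], len(used), axis=0)
        for i, f in enumerate(used):
            batch[i, :, f] = rng.permutation(X_oob[:, f])
        preds = tree.predict(batch.reshape(-1, p)).reshape(len(used), -1)
        increase[used] += np.mean((preds - y_oob[None, :]) ** 2, axis=1) - base_mse
    return increase / n_trees


def _rank_genes(X: np.ndarray, y: LabelSet, n_trees: int, seed: int) -> np.ndarray:
    """Stage-one gene ranking: Gini importance (classification) or OOB
    permutation MSE increase (regression). Returns importances, length p."""
    if y.is_classification:
        rf = _make_rf(X.shape[1], y, n_trees, seed)
        rf.fit(X, y.values)
        return rf.feature_importances_
    return _oob_permutation_importance_regression(X, y.values, n_trees, seed)


def fit(spec: ModelSpec, X: np.ndarray, y: LabelSet, seed: int = 0) -> FittedModel:
    """Fit one model specification on training data.

    All data-dependent choices (SVM tuning, PCA projection, gene screening,
    internal penalty paths) happen here, on (X, y) only — callers embed this
    in cross-validation folds without leaking test rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be samples × genes")
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if y.labeling_kind != spec.labeling_kind:
        raise ValueError(
            f"label set is {y.labeling_kind!r} but spec expects {spec.labeling_kind!r}"
        )
    hp = spec.resolved()
    classes = _check_classification(y) if y.is_classification else None
    model = FittedModel(spec=spec, estimator=None, classes_=classes, n_features_in_=p)

    algo = spec.algorithm
    if algo == "elastic_net":
        # features standardized before the penalized fit (the regularization
        # path convention); penalty strength from the internal CV path
        est = make_pipeline(
            StandardScaler(),
            ElasticNetCV(
                l1_ratio=0.5,
                alphas=hp["enet_alphas"],
                cv=min(hp["enet_cv"], n),
                random_state=derive_seed(seed, 11),
            ),
        )
        est.fit(X, y.values)
    elif algo == "l1_logistic":
        est = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=hp["logistic_Cs"],
                cv=min(hp["logistic_cv"], int(np.min(np.unique(y.values, return_counts=True)[1]))),
                l1_ratios=(1.0,),
                solver="liblinear",
                scoring="neg_log_loss",
                use_legacy_attributes=False,
                random_state=derive_seed(seed, 12),
            ),
        )
        est.fit(X, y.values)
        model.classes_ = est[-1].classes_
    elif algo in ("svm", "pca_svm", "rf", "pca_rf"):
        X_fit = X
        if algo.startswith("pca_"):
            k = min(hp["pca_components"], n, p)
            pca = PCA(n_components=k, random_state=derive_seed(seed, 13))
            X_fit = pca.fit_transform(X)
            model.pca_ = pca
            model.components = pca.components_
        if algo.endswith("svm"):
            grid = _svm_grid(X_fit.shape[1], hp, regression=not y.is_classification)
            params = tune_svm_nested(
                X_fit, y, grid, hp["svm_inner_k"], derive_seed(seed, 14), hp["svm_kernel"]
            )
            model.chosen_params = params
            est = _make_svm(params, y, hp["svm_kernel"])
            est.fit(X_fit, y.values)
        else:
            est = _make_rf(X_fit.shape[1], y, hp["n_trees"], derive_seed(seed, 15))
            est.fit(X_fit, y.values)
            if y.is_classification:
                model.classes_ = est.classes_
    elif algo == "two_stage_rf":
        importances = _rank_genes(X, y, hp["n_trees"], derive_seed(seed, 16))
        top = min(hp["top_genes"], p)
        # stable ranking: importance descending, gene index ascending on ties
        order = np.lexsort((np.arange(p), -importances))
        selected = np.sort(order[:top])
        model.selected_features = selected
        est = _make_rf(len(selected), y, hp["n_trees"], derive_seed(seed, 17))
        est.fit(X[:, selected], y.values)
        if y.is_classification:
            model.classes_ = est.classes_
    else:  # pragma: no cover
        raise ValueError(f"unhandled algorithm {algo!r}")
    model.estimator = est
    return model
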