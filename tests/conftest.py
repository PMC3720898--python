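import numpy as np
import pytest
import sklearn

import pgxlearn as pg
from pgxlearn.labeling import make_label_sets

# all test inputs are finite by construction; skipping sklearn's per-fit
# finiteness scans keeps the permutation-heavy suite inside its runtime
sklearn.set_config(assume_finite=True)

# Hyperparameters scaled for test runtime: smaller forests / grids / paths.
# Structural settings (mtry rules, PCA components, top-gene cap, reciprocal
# class weights, nested tuning) are untouched.
FAST_HP = {
    "n_trees": 30,
    "svm_C": (1.0, 10.0),
    "svm_gamma_scale": (1.0,),
    "svm_epsilon": (0.1,),
    "svm_inner_k": 3,
    "enet_cv": 3,
    "enet_alphas": 30,
    "logistic_cv": 3,
    "logistic_Cs": 5,
}


@pytest.fixture(scope="session")
def fast_hp():
    return dict(FAST_HP)


@pytest.fixture(scope="session")
def small_panel():
    """60-sample × 120-gene latent-state panel shared across tests."""
    return pg.generate_state_panel(n_samples=60, n_genes=120, n_states=5, noise_sd=0.5, seed=3)


@pytest.fixture(scope="session")
def small_panel_xy(small_panel):
    """Aligned (X, label sets) for both control drugs of the small panel."""
    em = small_panel.expression_matrix()
    rp = small_panel.response_panel()
    out = {}
    for drug in ("state1", "state0"):
        X, y, _ = pg.align_panel(em, rp, drug)
        out[drug] = (X, make_label_sets(y))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
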