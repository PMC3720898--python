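"""How does prediction error degrade as the cell-line panel shrinks?

Evaluates random-forest regression on the positive-control drug while
removing five random samples at a time (down to 20). The median RMSE drifts
up only mildly, but the spread across CV repetitions widens — the hallmark
of unstable error estimates at small n.
"""

import numpy as np

import pgxlearn as pg
from pgxlearn.labeling import make_label_sets
from pgxlearn.models import ModelSpec

panel = pg.generate_state_panel(n_samples=59, n_genes=80, n_states=5, noise_sd=0.5, seed=2)
X, y_cont, _ = pg.align_panel(panel.expression_matrix(), panel.response_panel(), "state1")
y = make_label_sets(y_cont)["regression"]

spec = ModelSpec("rf", "regression", {"n_trees": 50})
curve = pg.degradation_curve(spec, X, y, step=5, min_n=20, k=10, repeats=8, seed=0)

print(" n   median RMSE   IQR of per-repeat RMSE")
for n_used, result in curve:
    q25, q75 = np.percentile(result.valid, [25, 75])
    print(f"{n_used:3d}   {result.median:11.3f}   {q75 - q25:10.3f}")
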