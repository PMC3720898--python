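"""From IC50 measurements to the three prediction targets.

Converts molar IC50s to pIC50 and derives the regression / binary / 3-class
labelings. Thresholds come from the extreme-trimmed sample (values equal to
the global min or max are excluded from threshold computation only), so
assay-boundary pile-ups cannot drag the class cut points.
"""

import numpy as np

from pgxlearn.labeling import make_label_sets, to_pic50

ic50_molar = [1e-5, 3e-6, 1e-6, 4e-7, 1e-7, 2e-8, 5e-9, 2e-10, 2e-10]
pic50 = np.array([to_pic50(v) for v in ic50_molar])
print("pIC50:", np.round(pic50, 2))

for kind, label_set in make_label_sets(pic50).items():
    if label_set is None:
        print(f"{kind}: unavailable")
    elif kind == "regression":
        print("regression: target = pIC50 itself")
    else:
        thr = ", ".join(f"{t:.2f}" for t in label_set.thresholds)
        print(f"{kind}: thresholds [{thr}] -> labels {label_set.values.tolist()}")
print(
    "\nLabel 1 = non-responder (low pIC50), top label = responder; "
    "ties at a threshold fall into the lower class."
)
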