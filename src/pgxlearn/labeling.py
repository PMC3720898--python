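"""IC50 → pIC50 conversion and the three prediction targets per drug.

A drug's measured IC50 values (mol/L) are first converted to the pIC50 scale,
pIC50 = −log10(IC50), so that larger means more potent. Each drug then yields
up to three targets ("labelings"):

* ``regression`` — the pIC50 vector itself;
* ``binary`` — responder (2) vs non-responder (1), split at a data-driven
  threshold: drop every value equal to the global minimum or maximum, take the
  median of what remains, label values strictly greater than it with 2;
* ``class3`` — responder (3) / intermediate (2) / non-responder (1), with the
  lower and upper thresholds at the 0.33- and 0.66-quantile of the same
  extreme-trimmed sample.

The extreme-trimming guards the thresholds against assay-boundary pile-ups
(IC50s censored at the tested concentration range); trimmed samples are still
labeled and returned — trimming only affects threshold computation.

Quantiles use linear interpolation of order statistics (h = (m−1)q + 1), and
the even-length median is the mean of the two middle order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabelSet",
    "LabelingError",
    "LABELING_KINDS",
    "to_pic50",
    "label_binary",
    "label_ternary",
    "make_label_sets",
]

LABELING_KINDS = ("regression", "binary", "class3")


class LabelingError(ValueError):
    """Raised when a labeling is undefined for the given pIC50 sample."""


@dataclass(frozen=True)
class LabelSet:
    """One prediction target: continuous pIC50 or integer class labels.

    ``thresholds`` records the cut points actually used, in pIC50 units:
    ``()`` for regression, ``(t,)`` for binary, ``(lower, upper)`` for class3.
    """

    labeling_kind: str
    values: np.ndarray
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.labeling_kind not in LABELING_KINDS:
            raise ValueError(f"unknown labeling kind {self.labeling_kind!r}")
        vals = np.asarray(self.values)
        if self.labeling_kind == "regression":
            vals = vals.astype(float)
            if not np.all(np.isfinite(vals)):
                raise ValueError("regression targets must be finite")
        else:
            vals = vals.astype(int)
            allowed = {1, 2} if self.labeling_kind == "binary" else {1, 2, 3}
            if not set(np.unique(vals)) <= allowed:
                raise ValueError(f"labels outside {sorted(allowed)}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_classification(self) -> bool:
        return self.labeling_kind != "regression"

    def permuted(self, rng: np.random.Generator) -> "LabelSet":
        """A copy with the target values uniformly permuted (null-model input)."""
        perm = rng.permutation(len(self.values))
        return LabelSet(self.labeling_kind, self.values[perm], self.thresholds)


def to_pic50(ic50: float) -> float:
    """Convert an IC50 in mol/L to pIC50 = −log10(IC50). Requires ic50 > 0."""
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50!r}")
    return -math.log10(ic50)


def _trim_extremes(pic50: np.ndarray) -> np.ndarray:
    if len(pic50) == 0:
        raise LabelingError("empty pIC50 vector")
    if not np.all(np.isfinite(pic50)):
        raise LabelingError("pIC50 vector contains non-finite values")
    lo, hi = pic50.min(), pic50.max()
    if lo == hi:
        raise LabelingError("all pIC50 values identical; thresholds undefined")
    remaining = pic50[(pic50 != lo) & (pic50 != hi)]
    if len(remaining) == 0:
        raise LabelingError("no samples remain after removing extremes")
    return remaining


def _quantile(sorted_vals: np.ndarray, q: float) -> float:
    # linear interpolation of order statistics, h = (m-1) q + 1
    return float(np.quantile(sorted_vals, q, method="linear"))


def label_binary(pic50: np.ndarray) -> LabelSet:
    """Binary responder labeling: 2 above the trimmed median, else 1."""
    pic50 = np.asarray(pic50, dtype=float)
    remaining = _trim_extremes(pic50)
    threshold = float(np.median(remaining))
    labels = np.where(pic50 > threshold, 2, 1)
    return LabelSet("binary", labels, (threshold,))


def label_ternary(pic50: np.ndarray) -> LabelSet:
    """Three-class labeling at the trimmed 0.33- and 0.66-quantiles."""
    pic50 = np.asarray(pic50, dtype=float)
    remaining = _trim_extremes(pic50)
    lower = _quantile(remaining, 0.33)
    upper = _quantile(remaining, 0.66)
    labels = np.full(len(pic50), 2, dtype=int)
    labels[pic50 > upper] = 3
    labels[pic50 < lower] = 1
    return LabelSet("class3", labels, (lower, upper))


def make_label_sets(pic50: np.ndarray) -> dict[str, LabelSet | None]:
    """All three labelings for one drug; classification entries are None when
    undefined (e.g. a constant pIC50 series), while regression always succeeds."""
    pic50 = np.asarray(pic50, dtype=float)
    out: dict[str, LabelSet | None] = {
        "regression": LabelSet("regression", pic50)
    }
    for kind, fn in (("binary", label_binary), ("class3", label_ternary)):
        try:
            out[kind] = fn(pic50)
        except LabelingError:
            out[kind] = None
    return out
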