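"""Permutation null distribution and empirical p-values.

Whether a cross-validated model truly extracts information from expression
data is decided against a label-permutation null: the identical learning
pipeline (including all in-fold tuning and feature selection) is re-run B
times on uniformly permuted response values, destroying any expression–
response association while preserving the response distribution. The
empirical p-value is

    p = (c + 1) / (B + 1),

with c the number of null performances at least as good as the real one
(ties count; ≤ for error metrics, ≥ for score metrics), so p is never zero
and its floor is 1/(B+1). The default B = 110 puts the floor at 1/111 ≈ 0.009.

The real statistic is the median over the repetitions of a repeated k-fold
CV; each null draw is a single k-fold CV. Hyperparameter tuning is re-run
inside every permutation — reusing the unpermuted model's tuned parameters
would bias the null optimistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import derive_seed, rng_from
from .evaluation import CVResult, cross_validate, metric_direction
from .labeling import LabelSet
from .models import ModelSpec

__all__ = ["PermutationNull", "permutation_null", "empirical_p", "evaluate_with_null"]

DEFAULT_B = 110  # p-value floor 1/111 ≈ 0.009

_MAX_RETRIES = 5


@dataclass
class PermutationNull:
    B: int
    null_values: np.ndarray
    metric_name: str
    direction: str  # lower_better | higher_better
    seed: int
    messages: list[str]

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.B:
            raise ValueError("null_values length must equal B")


def permutation_null(
    spec: ModelSpec,
    X: np.ndarray,
    y: LabelSet,
    B: int = DEFAULT_B,
    k: int = 10,
    seed: int = 0,
) -> PermutationNull:
    """B single k-fold CV runs of ``spec`` on uniformly permuted responses.

    Uniform sampling may (rarely) include the identity permutation; that is
    part of the sampling contract. A permutation whose CV metric is undefined
    (e.g. a degenerate fold) is logged and redrawn, with bounded retries.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    null_values = np.empty(B)
    messages: list[str] = []
    for b in range(B):
        value = np.nan
        for attempt in range(_MAX_RETRIES):
            rng = rng_from(seed, 3001, b, attempt)
            y_perm = y.permuted(rng)
            res = cross_validate(
                spec, X, y_perm, k=k, repeats=1, seed=derive_seed(seed, 3002, b, attempt)
            )
            if np.isfinite(res.per_repeat[0]):
                value = res.per_repeat[0]
                break
            messages.append(f"permutation {b} attempt {attempt} invalid; resampled")
        if not np.isfinite(value):
            raise RuntimeError(f"permutation {b}: metric undefined after {_MAX_RETRIES} retries")
        null_values[b] = value
    return PermutationNull(
        B=B,
        null_values=null_values,
        metric_name=spec.metric_name,
        direction=metric_direction(spec.metric_name),
        seed=seed,
        messages=messages,
    )


def empirical_p(real_statistic: float, null: PermutationNull) -> float:
    """p = (c + 1)/(B + 1), c = number of null values at least as good as the
    real statistic (ties included). Always in (0, 1]."""
    if not np.isfinite(real_statistic):
        raise ValueError("real statistic must be finite")
    if null.direction == "lower_better":
        c = int(np.sum(null.null_values <= real_statistic))
    else:
        c = int(np.sum(null.null_values >= real_statistic))
    return (c + 1) / (null.B + 1)


def evaluate_with_null(
    spec: ModelSpec,
    X: np.ndarray,
    y: LabelSet,
    B: int = DEFAULT_B,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[CVResult, PermutationNull, float]:
    """Real repeated-CV statistic, its permutation null, and the p-value.

    Returns ``(cv_result, null, p_value)``; the caller (experiments module)
    wraps these into a result-table record.
    """
    cv = cross_validate(spec, X, y, k=k, repeats=repeats, seed=derive_seed(seed, 3101))
    if not np.isfinite(cv.median):
        raise RuntimeError("real statistic undefined in every CV repetition")
    null = permutation_null(spec, X, y, B=B, k=k, seed=derive_seed(seed, 3102))
    return cv, null, empirical_p(cv.median, null)
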