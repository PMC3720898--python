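"""Selection of a representative drug subset from a large response screen.

Large screens (tens of thousands of compounds) are reduced to a tractable,
diverse subset in four steps:

1. **Filter** — drop drugs with more than 5 missing cell-line values or fewer
   than 29 distinct observed values (near-constant response profiles carry no
   signal to learn).
2. **Standardize** — per drug, subtract the mean and divide by the mean
   absolute deviation about the mean (a robust scale for heavy-tailed
   potency profiles).
3. **Cluster** — CLARA k-medoids (default k = 30) on Euclidean distances
   between drug response profiles: PAM (build + swap) is run on repeated
   random subsamples (default 50 subsamples of 500 drugs), every drug is
   assigned to its nearest medoid, and the best-cost medoid set wins.
   Later subsamples always contain the incumbent best medoids.
4. **Select** — the medoids of the 14 largest clusters become the
   representative drugs.

Missing entries that survive the filter enter the distance as
pairwise-complete Euclidean distance rescaled by √(total dims / observed
dims).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import rng_from
from .io import ResponsePanel

__all__ = [
    "ClaraResult",
    "filter_drugs",
    "standardize_response",
    "standardize_panel",
    "response_distance_matrix",
    "pam",
    "cluster_drugs_clara",
    "select_representatives",
]


def filter_drugs(
    panel: ResponsePanel, max_missing: int = 5, min_distinct: int = 29
) -> ResponsePanel:
    """Keep drugs with ≤ ``max_missing`` missing and ≥ ``min_distinct`` distinct values."""
    keep = [
        c
        for c in panel.compounds
        if panel.n_missing(c) <= max_missing and panel.n_distinct(c) >= min_distinct
    ]
    return ResponsePanel(panel.pic50.loc[keep])


def standardize_response(series) -> np.ndarray:
    """(y − mean) / meanAD with meanAD = mean |y − mean|; NaN passes through."""
    arr = np.asarray(series, dtype=float)
    obs = arr[np.isfinite(arr)]
    if len(obs) == 0:
        raise ValueError("no observed values")
    mean = obs.mean()
    mean_ad = np.mean(np.abs(obs - mean))
    if mean_ad == 0:
        raise ValueError("constant series: mean absolute deviation is zero")
    return (arr - mean) / mean_ad


def standardize_panel(panel: ResponsePanel) -> ResponsePanel:
    rows = {c: standardize_response(panel.pic50.loc[c]) for c in panel.compounds}
    return ResponsePanel(
        pd.DataFrame(rows, index=panel.cell_lines).T.set_axis(panel.compounds)
    )


def response_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distance between rows, rescaled by
    √(total dims / observed dims); raises if two rows share no observed dim."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    sq = filled**2
    # pairwise sums over jointly observed dims
    joint = mask.astype(float) @ mask.T.astype(float)
    if np.any(joint == 0):
        raise ValueError("two drugs share no observed cell line")
    cross = filled @ filled.T
    a2 = sq @ mask.T.astype(float)
    d2 = a2 + a2.T - 2 * cross
    d2 = np.maximum(d2 * (p / joint), 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int]) -> list[int]:
    n = dist.shape[0]
    medoids = list(medoids)
    improved = True
    while improved:
        improved = False
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = medoids[:mi] + medoids[mi + 1 :]
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = dist[:, others + [h]].min(axis=1).sum() if others else dist[:, h].sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            improved = True
    return medoids


def pam(dist: np.ndarray, k: int, init: list[int] | None = None) -> tuple[list[int], float]:
    """Partitioning around medoids: greedy build (or a supplied initial medoid
    set), then best-improvement swaps to a local optimum. Returns
    (medoid indices, total cost)."""
    if k > dist.shape[0]:
        raise ValueError("k exceeds number of points")
    start = list(init) if init is not None else _pam_build(dist, k)
    medoids = _pam_swap(dist, start)
    cost = float(dist[:, medoids].min(axis=1).sum())
    return sorted(medoids), cost


def pam_exhaustive(dist: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact k-medoids by enumeration of all medoid subsets (oracle; tiny n only)."""
    n = dist.shape[0]
    best_cost, best_medoids = np.inf, None
    for subset in combinations(range(n), k):
        cost = dist[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, list(subset)
    return best_medoids, float(best_cost)


@dataclass
class ClaraResult:
    assignments: dict[str, int]  # drug -> cluster id (1..k)
    medoid_ids: list[str]  # cluster i's medoid is medoid_ids[i-1]
    cluster_sizes: list[int]
    total_cost: float
    seed: int


def cluster_drugs_clara(
    panel: ResponsePanel,
    k: int = 30,
    n_subsamples: int = 50,
    subsample_size: int = 500,
    seed: int = 0,
) -> ClaraResult:
    """CLARA k-medoids over drug response profiles (expects a standardized panel).

    Each round draws a random subsample (always including the incumbent best
    medoids), solves it with PAM, assigns every drug to its nearest medoid
    and scores the full-data cost; the best-cost solution over all rounds is
    returned. When the subsample covers the whole panel the rounds act as
    random restarts of the PAM swap phase (the first round uses the greedy
    build), so repeated rounds still escape swap local optima. Fully seeded.
    """
    drugs = panel.compounds
    n = len(drugs)
    if n < k:
        raise ValueError(f"need at least k={k} drugs, got {n}")
    values = panel.pic50.to_numpy(dtype=float)
    dist = response_distance_matrix(values)
    rng = rng_from(seed, 41)
    size = min(subsample_size, n)
    best_cost, best_medoids = np.inf, None
    for round_idx in range(n_subsamples):
        if best_medoids is None or size >= n:
            sample = rng.choice(n, size=size, replace=False)
        else:
            pool = np.setdiff1d(np.arange(n), best_medoids)
            extra = rng.choice(pool, size=size - len(best_medoids), replace=False)
            sample = np.concatenate([best_medoids, extra])
        sample = np.sort(sample)
        init = None
        if round_idx > 0:
            init = list(rng.choice(len(sample), size=k, replace=False))
        sub_medoids, _ = pam(dist[np.ix_(sample, sample)], k, init=init)
        medoids = sample[sub_medoids]
        cost = float(dist[:, medoids].min(axis=1).sum())
        if cost < best_cost - 1e-12:
            best_cost, best_medoids = cost, np.sort(medoids)
    assignment_idx = np.argmin(dist[:, best_medoids], axis=1)
    # ensure each medoid belongs to its own cluster even under distance ties
    for ci, m in enumerate(best_medoids):
        assignment_idx[m] = ci
    sizes = [int(np.sum(assignment_idx == ci)) for ci in range(k)]
    total_cost = float(
        sum(dist[i, best_medoids[assignment_idx[i]]] for i in range(n))
    )
    return ClaraResult(
        assignments={drugs[i]: int(assignment_idx[i]) + 1 for i in range(n)},
        medoid_ids=[drugs[m] for m in best_medoids],
        cluster_sizes=sizes,
        total_cost=total_cost,
        seed=seed,
    )


def select_representatives(result: ClaraResult, n_clusters: int = 14) -> list[str]:
    """Medoids of the ``n_clusters`` largest clusters; size ties break toward
    the lower cluster id. Never returns duplicates."""
    k = len(result.medoid_ids)
    if n_clusters > k:
        raise ValueError("n_clusters exceeds number of clusters")
    order = sorted(range(k), key=lambda ci: (-result.cluster_sizes[ci], ci))
    reps: list[str] = []
    for ci in order[:n_clusters]:
        m = result.medoid_ids[ci]
        if m not in reps:
            reps.append(m)
    return reps
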