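"""Meta-analysis of the p-value table: which factors drive predictability?

The summary table assigns one empirical p-value to every (compound, panel,
model, labeling) combination. Two complementary views rank these four
categorical factors:

* a **regression tree** on the p-values, whose early splits expose the
  dominant factors and whose leaves summarize mean p-value per partition;
* a **random-forest importance ranking** — out-of-bag permutation importance
  (mean OOB MSE increase when one factor's column is permuted as a unit,
  reported as a raw fraction, negatives possible for pure noise) and node
  purity importance (total squared-error reduction from splits on the
  factor, averaged over trees).

Both use native categorical splits: candidate binary splits partition a
factor's levels into two subsets, searched exactly by ordering levels by
their mean response (optimal for squared-error regression trees). Factor
levels here are few (≤ 30), so the search is cheap and reproducible.

``cross_panel_agreement`` quantifies whether two panels even measure the same
drug response: Pearson correlation (with two-sided p) and RMSE over the
shared, jointly observed cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import derive_seed

__all__ = [
    "FACTORS",
    "TreeNode",
    "TreeSummary",
    "FactorImportance",
    "fit_factor_tree",
    "factor_importance_rf",
    "cross_panel_agreement",
]

FACTORS = ("compound", "panel", "model", "labeling")

# S1-schema column aliases accepted for the four factors
_ALIASES = {"expSet": "panel"}


def _prepare(records: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    df = records.rename(columns=_ALIASES).copy()
    missing = [f for f in FACTORS if f not in df.columns]
    if missing:
        raise ValueError(f"missing factor columns: {missing}")
    if "p_value" not in df.columns:
        raise ValueError("missing p_value column")
    df = df.dropna(subset=["p_value"])
    if len(df) == 0:
        raise ValueError("empty record table")
    y = df["p_value"].to_numpy(dtype=float)
    return df[list(FACTORS)].astype(str).reset_index(drop=True), y


def _best_split(col: pd.Series, y: np.ndarray) -> tuple[float, frozenset] | None:
    """Best binary subset split of one categorical column by SS reduction.

    Levels are ordered by mean response; only prefix splits of that ordering
    need checking (exact for squared-error). Returns (reduction, left-levels)
    or None if the column is constant.
    """
    groups = pd.Series(y).groupby(col.to_numpy(), sort=True)
    means = groups.mean()
    if len(means) < 2:
        return None
    order = means.sort_values(kind="stable").index.to_numpy()
    sums = groups.sum().reindex(order).to_numpy()
    counts = groups.count().reindex(order).to_numpy().astype(float)
    tot_sum, tot_n = y.sum(), float(len(y))
    parent_ss_term = tot_sum**2 / tot_n
    cum_sum = np.cumsum(sums)[:-1]
    cum_n = np.cumsum(counts)[:-1]
    # SS reduction = sum_child (S_c^2/n_c) - S^2/n
    red = cum_sum**2 / cum_n + (tot_sum - cum_sum) ** 2 / (tot_n - cum_n) - parent_ss_term
    best = int(np.argmax(red))
    return float(red[best]), frozenset(order[: best + 1])


@dataclass
class TreeNode:
    n: int
    mean: float
    factor: str | None = None  # None for leaves
    left_levels: frozenset = frozenset()
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.factor is None


@dataclass
class TreeSummary:
    root: TreeNode
    n_total: int

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def root_split_factor(self) -> str | None:
        return self.root.factor

    def render(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, prefix: str) -> None:
            if node.is_leaf:
                pct = 100.0 * node.n / self.n_total
                lines.append(f"{prefix}leaf: mean p = {node.mean:.3f}, n = {node.n} ({pct:.0f}%)")
            else:
                lines.append(
                    f"{prefix}split on {node.factor}: {{{', '.join(sorted(node.left_levels))}}}"
                )
                walk(node.left, prefix + "  ")
                walk(node.right, prefix + "  ")

        walk(self.root, "")
        return "\n".join(lines)


def fit_factor_tree(
    records: pd.DataFrame, min_leaf: int = 20, complexity: float = 0.01
) -> TreeSummary:
    """CART-style regression tree of p_value on the four categorical factors.

    A split is kept when both children hold at least ``min_leaf`` records and
    the squared-error reduction is at least ``complexity`` times the root sum
    of squares. Deterministic: exhaustive exact split search, no sampling.
    """
    df, y = _prepare(records)
    root_ss = float(np.sum((y - y.mean()) ** 2))
    threshold = complexity * root_ss if root_ss > 0 else np.inf

    def grow(idx: np.ndarray) -> TreeNode:
        y_node = y[idx]
        node = TreeNode(n=len(idx), mean=float(y_node.mean()))
        if len(idx) < 2 * min_leaf:
            return node
        best: tuple[float, str, frozenset] | None = None
        for factor in FACTORS:
            cand = _best_split(df[factor].iloc[idx], y_node)
            if cand is None:
                continue
            red, left_levels = cand
            if best is None or red > best[0]:
                best = (red, factor, left_levels)
        if best is None or best[0] < threshold:
            return node
        red, factor, left_levels = best
        mask = df[factor].iloc[idx].isin(left_levels).to_numpy()
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return node
        node.factor = factor
        node.left_levels = left_levels
        node.left = grow(idx[mask])
        node.right = grow(idx[~mask])
        return node

    return TreeSummary(root=grow(np.arange(len(y))), n_total=len(y))


@dataclass
class FactorImportance:
    pct_inc_mse: dict[str, float]  # raw OOB MSE increase (fraction scale)
    inc_node_purity: dict[str, float]  # SS reduction per factor, averaged over trees
    n_trees: int
    seed: int

    def ranking(self, measure: str = "inc_node_purity") -> list[str]:
        values = getattr(self, measure)
        return sorted(FACTORS, key=lambda f: -values[f])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "%IncMSE": [self.pct_inc_mse[f] for f in FACTORS],
                "IncNodePurity": [self.inc_node_purity[f] for f in FACTORS],
            },
            index=list(FACTORS),
        )


# random-forest regression conventions: terminal node size 5, p/3 candidate
# factors per split (here max(1, 4//3) = 1)
_NODESIZE = 5


def _grow_random_tree(
    codes: np.ndarray, y: np.ndarray, idx: np.ndarray, rng: np.random.Generator,
    mtry: int, purity: np.ndarray
) -> list:
    """Recursive splitter over integer-coded factors; returns a nested node
    structure [factor, left_level_codes, left_child, right_child] or [mean]."""
    y_node = y[idx]
    if len(idx) <= _NODESIZE or np.ptp(y_node) == 0:
        return [float(y_node.mean())]
    candidates = rng.choice(len(FACTORS), size=mtry, replace=False)
    best = None
    for f in candidates:
        cand = _best_split(pd.Series(codes[idx, f]), y_node)
        if cand is None:
            continue
        red, left_levels = cand
        if best is None or red > best[0]:
            best = (red, int(f), left_levels)
    if best is None or best[0] <= 0:
        return [float(y_node.mean())]
    red, f, left_levels = best
    purity[f] += red
    mask = np.isin(codes[idx, f], list(left_levels))
    return [
        f,
        left_levels,
        _grow_random_tree(codes, y, idx[mask], rng, mtry, purity),
        _grow_random_tree(codes, y, idx[~mask], rng, mtry, purity),
    ]


def _tree_predict(node: list, codes_row: np.ndarray) -> float:
    while len(node) > 1:
        f, left_levels, left, right = node
        node = left if codes_row[f] in left_levels else right
    return node[0]


def factor_importance_rf(
    records: pd.DataFrame, n_trees: int = 500, seed: int = 0
) -> FactorImportance:
    """Random-forest regression of p_value on the four factors with OOB
    permutation importance (%IncMSE, raw) and node-purity importance."""
    df, y = _prepare(records)
    n = len(y)
    codes = np.column_stack([pd.factorize(df[f], sort=True)[0] for f in FACTORS])
    mtry = max(1, len(FACTORS) // 3)
    purity = np.zeros(len(FACTORS))
    mse_increase = np.zeros(len(FACTORS))
    mse_trees = np.zeros(len(FACTORS))
    rng = np.random.default_rng(derive_seed(seed, 61))
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = _grow_random_tree(codes, y, boot, rng, mtry, purity)
        if len(oob) == 0:
            continue
        base_pred = np.array([_tree_predict(tree, codes[i]) for i in oob])
        base_mse = float(np.mean((base_pred - y[oob]) ** 2))
        for f in range(len(FACTORS)):
            perm = rng.permutation(len(oob))
            permuted = codes[oob].copy()
            permuted[:, f] = codes[oob][perm, f]
            pred = np.array([_tree_predict(tree, row) for row in permuted])
            mse_increase[f] += float(np.mean((pred - y[oob]) ** 2)) - base_mse
            mse_trees[f] += 1
    return FactorImportance(
        pct_inc_mse={f: mse_increase[i] / max(mse_trees[i], 1) for i, f in enumerate(FACTORS)},
        inc_node_purity={f: purity[i] / n_trees for i, f in enumerate(FACTORS)},
        n_trees=n_trees,
        seed=seed,
    )


def cross_panel_agreement(
    series_a: pd.Series, series_b: pd.Series
) -> tuple[float, float, float, int]:
    """Pearson r (with two-sided p), RMSE and n over shared observed cell lines."""
    shared = sorted(
        set(series_a.index[series_a.notna()]) & set(series_b.index[series_b.notna()])
    )
    if len(shared) < 3:
        raise ValueError("need at least 3 shared observed cell lines")
    a = series_a[shared].to_numpy(dtype=float)
    b = series_b[shared].to_numpy(dtype=float)
    r, p = stats.pearsonr(a, b)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return float(r), float(p), rmse, len(shared)
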