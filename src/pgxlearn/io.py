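"""Expression / response containers, file formats and expression preprocessing.

Expression matrices follow the dominant microarray convention: genes in rows,
samples in columns, log2-scale intensities, TSV on disk with the sample ids as
header and the gene (or probe-set) identifier in the first column. Drug
response travels as a long-format CSV with columns ``compound``, ``cell_line``
and exactly one of ``ic50_molar`` / ``pic50``; in memory it is a compounds ×
cell-lines pIC50 matrix with NaN for missing measurements.

Preprocessing covers the two in-scope steps applied downstream of probe
summarisation: the elementwise log2 transform and the collapse of multiple
probe sets per gene symbol to the probe set with the largest mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .labeling import to_pic50

__all__ = [
    "ExpressionMatrix",
    "ResponsePanel",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_response_csv",
    "write_response_csv",
    "log2_transform",
    "collapse_probesets",
    "align_panel",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression. ``p`` (genes) may far exceed ``n`` (samples)."""

    values: pd.DataFrame  # index: gene symbols, columns: sample ids

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if cols.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        self.values = pd.DataFrame(arr, index=idx.astype(str), columns=cols.astype(str))

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes])


@dataclass
class ResponsePanel:
    """Compounds × cell lines pIC50 matrix (−log10 mol/L); NaN marks missing."""

    pic50: pd.DataFrame  # index: compounds, columns: cell lines

    def __post_init__(self) -> None:
        if self.pic50.index.has_duplicates:
            raise ValueError("duplicate compound identifiers")
        if self.pic50.columns.has_duplicates:
            raise ValueError("duplicate cell-line identifiers")
        arr = np.asarray(self.pic50, dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("observed pIC50 values must be finite")
        self.pic50 = pd.DataFrame(
            arr, index=self.pic50.index.astype(str), columns=self.pic50.columns.astype(str)
        )

    @property
    def compounds(self) -> list[str]:
        return list(self.pic50.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.pic50.columns)

    def series(self, compound: str) -> pd.Series:
        return self.pic50.loc[compound]

    def n_missing(self, compound: str) -> int:
        return int(self.pic50.loc[compound].isna().sum())

    def n_distinct(self, compound: str) -> int:
        return int(self.pic50.loc[compound].dropna().nunique())


def read_expression_tsv(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"duplicate sample ids in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def write_expression_tsv(matrix: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    """Write genes × samples TSV; values round-trip at 6 significant digits."""
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format=float_format)


def read_response_csv(path) -> ResponsePanel:
    """Read a long-format response CSV (compound, cell_line, ic50_molar|pic50)."""
    df = pd.read_csv(path, na_values=["NA", ""])
    cols = set(df.columns)
    if "pic50" in cols and "ic50_molar" in cols:
        raise ValueError("response CSV must carry exactly one of ic50_molar / pic50")
    if "pic50" in cols:
        df = df.assign(_pic50=df["pic50"].astype(float))
    elif "ic50_molar" in cols:
        ic50 = df["ic50_molar"].astype(float)
        df = df.assign(_pic50=[to_pic50(v) if np.isfinite(v) else np.nan for v in ic50])
    else:
        raise ValueError("response CSV needs an ic50_molar or pic50 column")
    wide = df.pivot_table(index="compound", columns="cell_line", values="_pic50", aggfunc="first")
    wide.index.name = None
    wide.columns.name = None
    return ResponsePanel(wide)


def write_response_csv(panel: ResponsePanel, path) -> None:
    long = (
        panel.pic50.rename_axis(index="compound", columns="cell_line")
        .stack(future_stack=True)
        .rename("pic50")
        .reset_index()
    )
    long.to_csv(path, index=False)


def log2_transform(values: np.ndarray | pd.DataFrame):
    """Elementwise log2; input must be strictly positive (linear-scale intensities)."""
    arr = np.asarray(values, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("log2 transform requires strictly positive values")
    out = np.log2(arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def collapse_probesets(values: pd.DataFrame, probe_map: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probes × samples to one row per gene symbol.

    For each symbol the probe set with the largest mean expression over all
    samples is retained; ties go to the lexicographically smallest probe id.
    Every probe row must appear in ``probe_map``.
    """
    unmapped = [p for p in values.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"unmapped probes: {unmapped[:5]}")
    means = values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(values.index):
        sym = probe_map[probe]
        if sym not in best or means[probe] > means[best[sym]]:
            best[sym] = probe
    symbols = sorted(best)
    out = values.loc[[best[s] for s in symbols]]
    out.index = symbols
    return ExpressionMatrix(out)


def align_panel(
    expr: ExpressionMatrix, resp: ResponsePanel, compound: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Restrict to cell lines present in both tables with an observed response.

    Returns ``(X, y, cell_lines)`` where X is samples × genes (learning
    orientation), y the matching pIC50 vector, both ordered by sorted
    cell-line id so the alignment is independent of input order.
    """
    series = resp.series(compound)
    shared = sorted(set(expr.sample_ids) & set(series.index[series.notna()]))
    if not shared:
        raise ValueError(f"no shared cell lines with observed response for {compound!r}")
    X = expr.values[shared].to_numpy(dtype=float).T
    y = series[shared].to_numpy(dtype=float)
    return X, y, shared
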