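"""Latent-state synthetic expression panel: positive and negative controls.

The generator emulates the virtual panel used to bracket predictability:
expression for ``n_genes`` genes over ``n_samples`` samples is driven by a
small number of latent state variables (default 5). Each gene is a fixed
random linear combination of the states plus i.i.d. Gaussian noise, giving
the p ≫ n regime of microarray data with known low-rank structure.

Two control "drugs" accompany the panel:

* ``state1`` — the continuous response equals the first latent state, so the
  expression matrix carries full information about it (positive control);
* ``state0`` — a seeded uniform permutation of ``state1``, which preserves the
  value multiset but destroys any expression–response association (negative
  control).

A well-calibrated evaluation pipeline must drive state1's empirical p-value
to its floor and leave state0's at chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_from
from .io import ExpressionMatrix, ResponsePanel

__all__ = ["SyntheticPanel", "generate_state_panel", "generate_response_fixture"]

STATE1 = "state1"
STATE0 = "state0"


@dataclass(frozen=True)
class SyntheticPanel:
    """Generated expression with its latent states and the two control responses."""

    expression: np.ndarray  # n_samples × n_genes
    states: np.ndarray  # n_samples × n_states
    response_state1: np.ndarray
    response_state0: np.ndarray
    seed: int

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]

    @property
    def gene_symbols(self) -> list[str]:
        return [f"G{j + 1:04d}" for j in range(self.n_genes)]

    def expression_matrix(self) -> ExpressionMatrix:
        """Genes × samples container, indistinguishable from a real panel downstream."""
        return ExpressionMatrix(
            pd.DataFrame(self.expression.T, index=self.gene_symbols, columns=self.sample_ids)
        )

    def response_panel(self) -> ResponsePanel:
        """Two-compound response panel holding the state1/state0 control drugs."""
        df = pd.DataFrame(
            [self.response_state1, self.response_state0],
            index=[STATE1, STATE0],
            columns=self.sample_ids,
        )
        return ResponsePanel(df)


def generate_state_panel(
    n_samples: int = 100,
    n_genes: int = 1000,
    n_states: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticPanel:
    """Generate the latent-state panel.

    States are i.i.d. standard normal; per-gene loadings are i.i.d. standard
    normal; expression = states · loadings + N(0, noise_sd²) noise. The
    response of the positive-control drug is the first latent state; the
    negative control is a uniform random permutation of it. Identical seeds
    give bit-identical panels.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if n_states < 1 or n_genes < n_states:
        raise ValueError("need n_genes >= n_states >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng_states = rng_from(seed, 1)
    rng_weights = rng_from(seed, 2)
    rng_noise = rng_from(seed, 3)
    rng_perm = rng_from(seed, 4)

    states = rng_states.standard_normal((n_samples, n_states))
    weights = rng_weights.standard_normal((n_states, n_genes))
    expression = states @ weights
    if noise_sd > 0:
        expression = expression + noise_sd * rng_noise.standard_normal(expression.shape)
    response = states[:, 0].copy()
    permuted = response[rng_perm.permutation(n_samples)]
    return SyntheticPanel(expression, states, response, permuted, int(seed))


def generate_response_fixture(
    n_drugs: int,
    n_cell_lines: int,
    missing_per_drug,
    distinct_per_drug,
    seed: int = 0,
) -> ResponsePanel:
    """Response panel with exact per-drug missingness and distinct-value counts.

    Plumbing for exercising the drug-selection filters: drug ``i`` gets exactly
    ``missing_per_drug[i]`` missing entries and exactly ``distinct_per_drug[i]``
    distinct observed pIC50 values among its observed cell lines.
    """
    missing = np.broadcast_to(np.asarray(missing_per_drug, dtype=int), (n_drugs,))
    distinct = np.broadcast_to(np.asarray(distinct_per_drug, dtype=int), (n_drugs,))
    for i in range(n_drugs):
        n_obs = n_cell_lines - missing[i]
        if missing[i] < 0 or distinct[i] < 1 or distinct[i] > n_obs:
            raise ValueError(
                f"drug {i}: inconsistent counts (missing={missing[i]}, "
                f"distinct={distinct[i]}, cell lines={n_cell_lines})"
            )
    rng = rng_from(seed, 10)
    cell_lines = [f"CL{i + 1:03d}" for i in range(n_cell_lines)]
    rows = []
    for i in range(n_drugs):
        n_obs = n_cell_lines - missing[i]
        # distinct base values, then pad by repeating the first value
        base = np.round(np.sort(rng.uniform(4.0, 9.0, size=distinct[i])), 4)
        while len(np.unique(base)) < distinct[i]:  # guard against rounding collisions
            base = np.round(np.sort(rng.uniform(4.0, 9.0, size=distinct[i])), 4)
        values = np.concatenate([base, np.full(n_obs - distinct[i], base[0])])
        rng.shuffle(values)
        row = np.concatenate([values, np.full(missing[i], np.nan)])
        rng.shuffle(row)
        rows.append(row)
    df = pd.DataFrame(rows, index=[f"D{i + 1:03d}" for i in range(n_drugs)], columns=cell_lines)
    return ResponsePanel(df)
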