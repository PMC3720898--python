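"""Seed plumbing shared by every stochastic component.

All randomness in the package flows through :func:`derive_seed`, which maps a
base seed plus a tuple of integer keys to an independent child seed via
``numpy.random.SeedSequence``. This keeps every stage (panel generation, CV
partitions, permutations, forest fits) reproducible and mutually independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "rng_from"]

_MOD = 2**31 - 1


def derive_seed(seed: int, *keys: int) -> int:
    """Deterministically derive a child seed (< 2**31) from ``seed`` and ``keys``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % _MOD)


def rng_from(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *keys))
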