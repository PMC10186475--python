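"""Seed-tree utilities.

Every simulator in this package derives its random state from a single
root seed through :func:`child_rng`.  Child ``k`` of root seed ``s`` is
``numpy.random.SeedSequence(s, spawn_key=(k,))``, so any fixture can be
regenerated in isolation without replaying the whole stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_rngs"]


def child_rng(seed: int, index: int = 0) -> np.random.Generator:
    """Return the ``index``-th child generator of a root ``seed``."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Return the first ``n`` child generators of a root ``seed``."""
    return [child_rng(seed, i) for i in range(n)]
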