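"""Seed derivation helpers.

All stochastic operations in the package flow from a single integer seed.
Sub-seeds (per subject, per repetition, per realization) are derived through
``numpy.random.SeedSequence`` so that partial reruns are reproducible and
independent streams do not collide.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seeds", "rng_from"]


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer sub-seeds from ``seed``."""
    state = np.random.SeedSequence(seed).generate_state(n, np.uint32)
    return [int(s >> 1) for s in state]


def rng_from(seed: int) -> np.random.Generator:
    """A fresh ``numpy`` Generator seeded deterministically from ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed))
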