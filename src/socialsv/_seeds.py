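"""Deterministic seed derivation.

Every stochastic routine takes a numpy Generator or an integer seed; stage
seeds are derived from one master seed salted with the stage name so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

RNGLike = int | np.random.Generator | None


def as_rng(rng: RNGLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage-name-salted 31-bit seed derived from a master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def spawn(rng: RNGLike, n: int) -> list[np.random.Generator]:
    """n independent child generators from one parent (order-stable)."""
    parent = as_rng(rng)
    seeds = parent.integers(0, 2**31, size=n)
    return [np.random.default_rng(int(s)) for s in seeds]
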