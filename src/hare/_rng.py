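"""Deterministic seed derivation.

Every stochastic routine takes an integer seed and, where it needs several
independent streams, derives child seeds through :func:`spawn_seeds`. The
derivation is pure (SeedSequence based), so a master seed reproduces every
downstream stream bit-for-bit.
"""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from ``seed``."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % _MOD for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
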