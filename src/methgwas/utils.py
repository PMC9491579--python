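"""Small shared helpers (seed derivation, z-scoring)."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed", "zscore"]


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed for a named stage, derived from a global seed.

    Uses CRC32 of the label so the mapping is stable across interpreter
    sessions (unlike ``hash``). Result is < 2**31.
    """
    return int(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]).generate_state(1)[0] % (2**31))


def derive_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, label))


def zscore(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit (population) variance; errors on constants."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd
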