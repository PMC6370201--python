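"""Deterministic seed derivation.

Every source of randomness in the package (generator pulses, noise
injection, Monte-Carlo tests) flows from one master seed plus a tuple of
string/int keys, so a dataset or a grid run is reproducible end to end and
independent of execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def _key_word(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(master_seed: int, *keys: object) -> int:
    """Derive a sub-seed < 2**31 from ``master_seed`` and hashable keys.

    Stable across runs and platforms (crc32 of the key strings feeds a
    numpy SeedSequence).
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_word(k) for k in keys]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(master_seed: int, *keys: object) -> np.random.Generator:
    """A fresh Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *keys))
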