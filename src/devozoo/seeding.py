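"""Deterministic seed derivation.

A single base seed is fanned out into independent substreams by hashing the
base entropy with a structured spawn key, so twins, mutants and walks get
reproducible, order-independent random streams.
"""

from __future__ import annotations

import numpy as np


def derive_seed(base_seed: int, *keys: int) -> int:
    """Derive a child seed (< 2**31) from a base seed and integer keys."""
    ss = np.random.SeedSequence(entropy=int(base_seed),
                                spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def rng_for(base_seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(base_seed),
                               spawn_key=tuple(int(k) for k in keys)))
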