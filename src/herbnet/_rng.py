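"""Deterministic child-seed derivation.

One master seed drives a whole pipeline run; every (entity, phenotype)
proximity computation gets its own child seed derived from the master seed
and the entity labels, so results are reproducible and order-independent
(computations can be re-run or parallelised in any order without changing
any individual result).
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def child_seed(master_seed: int, *tokens: str) -> int:
    """Derive a reproducible child seed from a master seed and string tokens.

    The scheme is a CRC32 of the joined tokens mixed with the master seed by
    modular multiplication; it is stable across runs and platforms and keeps
    seeds in [0, 2**31).
    """
    crc = zlib.crc32("|".join(tokens).encode("utf-8"))
    return (master_seed * 1_000_003 + crc) % _MOD


def rng_from(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(int(seed_or_rng))
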