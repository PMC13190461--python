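"""Deterministic seed derivation.

One master seed drives every stochastic component. Independent streams are
derived from (master, *key) tuples via SeedSequence so that any fold, model
fit, or permutation replicate can be replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_ints(key) -> list[int]:
    out = []
    for part in key:
        if isinstance(part, str):
            out.append(zlib.crc32(part.encode("utf-8")))
        else:
            out.append(int(part) & 0xFFFFFFFF)
    return out


def child_rng(master_seed: int, *key) -> np.random.Generator:
    """A generator for the stream identified by ``key`` under ``master_seed``."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_key_ints(key)])
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *key) -> int:
    """A 31-bit integer seed for libraries that take plain int seeds."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *_key_ints(key)])
    return int(ss.generate_state(1)[0] % (2**31))
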