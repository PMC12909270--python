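"""Deterministic seed derivation.

Every stochastic stage derives its own seed from the master seed plus a
string / integer key path, so that stages (and windows within a stage) can
run in any order — or in parallel — and still reproduce the serial result.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *keys: int | str) -> int:
    """Derive a child seed (< 2**31) from ``master`` and a key path."""
    entropy = [int(master) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(master: int, *keys: int | str) -> np.random.Generator:
    """A ``numpy`` Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *keys))
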