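"""Counter-based random substreams.

Every stochastic operation derives its generator from the study seed plus a
stable structural key (stage name, dyad id, ...). Per-dyad results are then
reproducible independently of iteration order, and two stages never share a
stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    raise TypeError(f"substream key parts must be int or str, got {type(part)!r}")


def substream(seed: int, *key) -> np.random.Generator:
    """Generator for the substream identified by ``key`` under ``seed``."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(p) for p in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_generator(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
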