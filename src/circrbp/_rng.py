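"""Seeded random-stream management.

One integer seed drives a whole pipeline run; each stage draws from a named
substream so that stages are independently reproducible (re-running only the
split, say, does not disturb the shuffle stream).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a run seed.

    The substream key is derived from a CRC of the name, so the mapping is
    stable across sessions and platforms.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))
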