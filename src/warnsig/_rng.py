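"""Seed-substream helpers: all randomness flows from one study seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for a named substream of the study seed.

    Substreams are independent for distinct key tuples and reproducible
    across runs and platforms (keys are hashed with CRC32, not ``hash``).
    """
    hashed = [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, *hashed]))
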