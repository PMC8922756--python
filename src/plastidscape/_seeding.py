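"""Deterministic random streams derived from one user-facing seed.

Every stochastic operation in the package draws from a stream keyed by
(seed, *labels).  String labels are hashed with CRC32, which is stable
across processes (unlike Python's salted ``hash``), so a fixed seed gives
byte-identical outputs on every run.
"""

from __future__ import annotations

import random
import zlib

import numpy as np

__all__ = ["derive_rng", "derive_pyrandom"]


def _key_ints(keys) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf8")))
    return out


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """A numpy Generator for stream (seed, *keys)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_ints(keys)]))


def derive_pyrandom(seed: int, *keys) -> random.Random:
    """A stdlib Random for stream (seed, *keys) (for libraries wanting one)."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_ints(keys)])
    return random.Random(int(ss.generate_state(2, dtype=np.uint32)[0]))
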