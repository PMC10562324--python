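"""Reproducible random-number substreams.

Every stochastic operation in the pipeline draws from an independent
substream derived from a single master seed plus a stable key path
(e.g. ``(master_seed, iteration, "age")``). String keys are hashed with
CRC-32 so the mapping is stable across sessions and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "key_to_int"]


def key_to_int(key: int | str) -> int:
    """Map a key to a non-negative integer below 2**31."""
    if isinstance(key, (int, np.integer)):
        return int(key) % (2**31)
    return zlib.crc32(str(key).encode("utf-8")) % (2**31)


def substream(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Return an independent generator for ``(master_seed, *keys)``.

    Distinct key paths give statistically independent streams; the same
    path always yields the same stream.
    """
    entropy = [key_to_int(master_seed)] + [key_to_int(k) for k in keys]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
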