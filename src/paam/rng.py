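"""Deterministic RNG substreams.

One global integer seed deterministically derives every random stream in
the pipeline.  Substreams are keyed by (stage name, sample index, mesh
id, step, ...) so that results are reproducible and independent of the
order in which meshes, years or samples are executed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "key_int"]


def key_int(key: int | str) -> int:
    """Map a substream key to a non-negative 32-bit integer.

    Strings are hashed with CRC-32 (stable across processes, unlike the
    built-in ``hash``); integers are masked into the uint32 range.
    """
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key) & 0xFFFFFFFF


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """A fresh Generator for the substream identified by ``keys``."""
    entropy = [key_int(seed)] + [key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
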