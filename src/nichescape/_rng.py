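"""Seed fan-out.

All randomness in the package flows from a single integer master seed.
Named substreams are derived with :class:`numpy.random.SeedSequence` so that
adding a stage never perturbs the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key(name: str) -> int:
    # stable across processes and platforms (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_key(name), int(index))))


def subseed(seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(seed, name, index).integers(0, 2**31 - 1))
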