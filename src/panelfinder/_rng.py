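"""Seed bookkeeping.

All randomness in the package flows from a single integer root seed.
Each stochastic stage draws from a named substream so that changing the
number of draws in one stage (e.g. more SVM splits) never perturbs
another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def subseed(seed: int, name: str) -> int:
    """A deterministic 31-bit child seed for stage ``name``."""
    ss = np.random.SeedSequence([int(seed), _name_key(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stage, independent of sibling stages."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(name)]))
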