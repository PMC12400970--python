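"""Seeding helpers: named, independent random streams from one master seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """A reproducible generator for the named sub-stream of a master seed.

    Streams are independent across names (schedule, noise, gains, behavior,
    init, ...) so that modules can be re-run in isolation without disturbing
    each other's draws.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, *extra]))


def child_seed(seed: int, name: str, *extra: int) -> int:
    """A derived integer seed (< 2**31) for handing to other components."""
    return int(substream(seed, name, *extra).integers(0, 2**31 - 1))
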