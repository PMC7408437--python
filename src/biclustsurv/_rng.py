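"""Named random streams derived from one global integer seed.

Each consumer asks for a stream by name so that adding a new stream to a
simulator never perturbs draws from existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The stream name is folded into the seed sequence through a CRC32 of the
    name, so streams are stable across runs and independent across names.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, tag]))
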