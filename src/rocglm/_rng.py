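"""Seed fan-out: one master seed, independent named substreams.

Every stochastic stage (eye selection, bootstrap, cohort simulation, ...)
draws from its own substream so a stage can be reproduced in isolation
without replaying the stages before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of ``master_seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf-8"))])
    )
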