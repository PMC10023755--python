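"""Seed-substream derivation.

Every stage of the pipeline draws from its own :class:`numpy.random.Generator`
derived from one user seed plus a stage name (and an optional item index), so
each stage is reproducible in isolation and inserting a stage never perturbs
the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return a deterministic per-stage random generator.

    Parameters
    ----------
    seed : global user seed (any int; folded into 31 bits).
    stage : stage name, hashed with CRC-32 so distinct names give
        independent streams.
    index : item counter within the stage (slice number, composite pair, ...).
    """
    key = (
        int(seed) & _MASK31,
        zlib.crc32(stage.encode("utf-8")) & _MASK31,
        int(index) & _MASK31,
    )
    return np.random.default_rng(np.random.SeedSequence(key))
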