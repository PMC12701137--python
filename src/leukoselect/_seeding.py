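"""Deterministic sub-seed derivation.

A single global seed drives every stage of a run. Stage seeds are derived by
hashing (seed, stage name) and per-sample seeds by hashing (seed, index), so
stages can be re-run in isolation and datasets extended without reshuffling
existing samples.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic sub-seed for a named pipeline stage."""
    return zlib.crc32(f"{int(global_seed)}:{stage}".encode()) & _MASK


def sample_rng(seed: int, index: int) -> np.random.Generator:
    """Independent random stream for sample ``index`` of a dataset seeded by ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed) & _MASK, int(index))))
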