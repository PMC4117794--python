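"""Deterministic per-stage random streams from a single master seed.

Every stochastic stage derives its own independent stream keyed by a
stage name, so adding or reordering stages never perturbs the randomness
of the others.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master_seed: int, stage: str) -> int:
    """A stable 31-bit child seed for one named stage."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator seeded for one named stage of a pipeline."""
    return np.random.default_rng(stage_seed(master_seed, stage))
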