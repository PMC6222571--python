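"""Seed plumbing: one run seed, named per-stage sub-streams."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    """Stable sub-seed for a named stage, derived from the run seed.

    Uses CRC32 of the stage name so re-running one stage never perturbs
    another stage's draws.  Result is kept below 2**31.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage."""
    return np.random.default_rng(stage_seed(seed, stage))
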