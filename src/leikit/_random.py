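"""Seed plumbing: one independent stream per named pipeline stage."""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, derived from the master seed.

    Keying on the stage name means adding or reordering stages never
    silently changes another stage's stream.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))
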