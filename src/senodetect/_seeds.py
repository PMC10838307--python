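"""Deterministic expansion of a single user seed into per-stage streams.

A run is driven by one integer seed. Every stage (mask generation, table
sampling, training-set subsampling, ...) derives its own independent stream
as ``SeedSequence([seed, crc32(stage_name)])``, so adding a stage never
perturbs the draws of existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def child_seed_sequence(seed: int, stage: str) -> np.random.SeedSequence:
    """Return the seed sequence for *stage* under the global *seed*."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf8"))])


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a ``numpy`` generator dedicated to *stage*."""
    return np.random.default_rng(child_seed_sequence(seed, stage))
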