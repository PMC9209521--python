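"""Deterministic per-stage random streams.

Every stochastic stage of the pipeline (splitting, bootstrap, permutation,
simulation, ...) draws from its own substream derived from the single run
seed and a stage name, so any stage can be reproduced in isolation and
adding a stage never perturbs the streams of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a 31-bit integer seed for a named stage from the run seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode("utf-8")),))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A `numpy` Generator seeded for the named stage."""
    return np.random.default_rng(stage_seed(seed, stage))
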