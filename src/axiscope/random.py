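"""Seeded random substreams.

All randomness in the package flows from a single integer seed through
named substreams, so stages (subsampling, count simulation, proportion
noise, ...) are independently reproducible and adding a stage never
perturbs another stage's draws.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stage, derived from the run seed.

    The stream is keyed by ``(seed, crc32(name))`` through a
    ``SeedSequence``, so distinct names yield statistically independent
    streams and the mapping is stable across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
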