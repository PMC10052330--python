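"""Named random substreams derived from a single global seed.

Every stochastic stage (simulation, bootstrapping, feature sampling, PSO)
draws its generator from :func:`substream`, so one integer seed fixes the
whole pipeline while stages stay statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for stage ``name``."""
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]).generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """A Generator seeded by (seed, name); same pair always yields the same stream."""
    return np.random.default_rng(substream_seed(seed, name))
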