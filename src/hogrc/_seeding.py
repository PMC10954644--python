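"""Deterministic substream derivation from one master seed.

Every stochastic component (initial conditions, network weights, reservoir
matrices, forecast anchors, noise) draws from its own named substream, so
changing e.g. the noise realisation never perturbs the reservoir matrices.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(tag) -> int:
    return zlib.crc32(repr(tag).encode("utf8"))


def seed_sequence(master_seed: int, *tags) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF] + [_key(t) for t in tags]
    )


def rng(master_seed: int, *tags) -> np.random.Generator:
    """A Generator keyed by the master seed plus any hashable tags."""
    return np.random.default_rng(seed_sequence(master_seed, *tags))
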