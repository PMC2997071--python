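"""Reproducible random-number streams.

One root seed deterministically spawns independent named substreams via
``numpy.random.SeedSequence`` spawn keys.  A path with id ``j`` always uses
the stream keyed ``(j,)`` regardless of how many other paths are generated,
which makes ensembles order-independent and bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def substream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream of ``seed`` named by the integer ``key``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def as_generator(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
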