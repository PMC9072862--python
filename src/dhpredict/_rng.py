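"""Deterministic RNG stream derivation.

Every stochastic operation in the package takes either an explicit
:class:`numpy.random.Generator` or an integer seed.  Orchestration code
derives independent child streams from one master seed with
:func:`rng_for`, keyed by small integer tags, so that replicate k of a
scenario uses the same stream whether replicates run serially, in a
different order, or in parallel.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_for", "as_rng"]


def rng_for(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *key)``.

    Uses :class:`numpy.random.SeedSequence` with ``key`` as spawn key, so
    distinct keys yield statistically independent, reproducible streams.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def as_rng(rng_or_seed) -> np.random.Generator:
    """Coerce ``None``, an int seed, or a Generator to a Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
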