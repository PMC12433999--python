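"""Seed-splitting scheme.

All randomness in the package flows from a single integer seed.  Independent
substreams are derived with :class:`numpy.random.SeedSequence` spawn keys, one
integer code per pipeline stage (plus optional extra integers such as the
replicate index).  The codes are fixed constants so that every stage is
reproducible in isolation.
"""
from __future__ import annotations

import numpy as np

# stage codes for spawn keys; never renumber
STREAM = {
    "structure": 0,   # village/interviewer assignment
    "sizes": 1,       # household size draws
    "effects": 2,     # latent random effects u, v, w
    "outcomes": 3,    # Bernoulli outcome draws
    "sex": 4,         # interviewer sex draws
    "attrition": 5,   # MAR dropout draws
    "impute": 6,      # sKNN stochastic votes / coin flips
    "replicate": 7,   # experiment replicate split
}


def substream(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Return the RNG for one named stage of the pipeline."""
    key = (STREAM[stage],) + tuple(int(e) for e in extra)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def replicate_seed(seed: int, replicate: int) -> int:
    """A derived integer seed (< 2**31) for one experiment replicate."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAM["replicate"], int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def derived_seed(seed: int, stage: str, *extra: int) -> int:
    """A derived integer seed (< 2**31) for a named stage (and optional indices)."""
    key = (STREAM[stage],) + tuple(int(e) for e in extra)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
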