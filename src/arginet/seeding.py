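"""Deterministic seed-substream derivation.

A single master seed drives the whole pipeline. Each stage draws from its
own substream, derived via :class:`numpy.random.SeedSequence` spawn keys,
so that e.g. count simulation and proteome simulation with the same master
seed are decorrelated yet individually reproducible.
"""
from __future__ import annotations

import numpy as np

# Fixed stream ids; appending new stages must not renumber existing ones,
# or previously published seeds change meaning.
_STREAMS = {
    "design": 0,
    "counts": 1,
    "pathways": 2,
    "proteome": 3,
    "network": 4,
    "isotopologues": 5,
    "impute": 6,
    "pathperm": 7,
    "sam": 8,
    "subgraph": 9,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named per-stage generator for a master ``seed``."""
    if name not in _STREAMS:
        raise KeyError(f"unknown random stream {name!r}")
    ss = np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[name],))
    return np.random.default_rng(ss)
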