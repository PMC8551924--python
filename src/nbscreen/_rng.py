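"""Labeled child RNG streams.

A single root seed drives the whole pipeline; each stochastic component draws
from its own child stream identified by a fixed label, so e.g. enlarging the
drug library never perturbs the copy-number draws.
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "copy_number": 1,
    "drug_response": 2,
    "variants": 3,
    "library": 4,
    "fi_network": 5,
    "permutation": 6,
    "planting": 7,
}


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return the deterministic child generator for a named component."""
    if label not in _STREAMS:
        raise KeyError(f"unknown RNG stream label: {label!r}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[label],))
    return np.random.default_rng(ss)
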