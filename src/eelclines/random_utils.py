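"""Deterministic seed derivation.

A single user-facing integer seed is expanded into independent streams by
hashing string labels (CRC-32) into a :class:`numpy.random.SeedSequence`
alongside the base seed.  The rule is purely arithmetic, so any module can
be re-run in isolation and reproduce the stream it received inside a full
pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(base_seed: int, *labels: str | int) -> np.random.SeedSequence:
    """SeedSequence for stream ``labels`` under ``base_seed``."""
    keys = [int(base_seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, int):
            keys.append(lab & 0x7FFFFFFF)
        else:
            keys.append(zlib.crc32(lab.encode("utf-8")) & 0x7FFFFFFF)
    return np.random.SeedSequence(keys)


def rng_for(base_seed: int, *labels: str | int) -> np.random.Generator:
    """Generator seeded for the stream named by ``labels``."""
    return np.random.default_rng(derive_seed(base_seed, *labels))
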