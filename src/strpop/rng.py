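"""Deterministic random-stream management.

A single global seed expands into independent per-operation substreams by
stable hashing of the operation name, so adding randomness to one stage
never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Generator for operation ``name`` derived from the global ``seed``.

    The same (seed, name, index) triple always yields the same stream;
    distinct names or indices yield statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(index)]))
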