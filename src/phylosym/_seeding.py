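"""Named random substreams.

All stochastic steps (rarefaction, capping, representative choice, permutation
tests, simulation) draw from a `numpy.random.Generator` derived from a single
root seed and a stream name, so a pipeline run is bit-reproducible from one
integer and independent stages do not share state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    ``None`` gives fresh OS entropy (non-reproducible); otherwise the stream is
    a deterministic function of ``(seed, name)`` via a CRC32 spawn key.
    """
    if seed is None:
        return np.random.default_rng()
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
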