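"""Seed-substream management.

All stochastic routines in the package draw from :class:`numpy.random.Generator`
instances derived from a single master seed through named substreams, so that
each module's randomness is reproducible independently of call order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(part) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    return int(part) & 0x7FFFFFFF


def substream(seed: int, *path) -> np.random.Generator:
    """Return an independent generator for the substream named by ``path``.

    Parameters
    ----------
    seed
        Master seed of the run.
    path
        Any mix of strings and integers naming the substream, e.g.
        ``substream(1, "meiosis", chrom)``. Distinct paths yield
        statistically independent streams; the same path always yields
        the same stream.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key(p) for p in path]
    return np.random.default_rng(np.random.SeedSequence(entropy))
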