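"""Deterministic, order-independent random streams.

Every stochastic routine in the package accepts either an integer seed or a
``numpy.random.Generator``.  Pipeline stages that loop over many series derive
one independent substream per series from a single master seed by hashing the
series labels, so results do not depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["as_generator", "series_stream"]


def as_generator(seed) -> np.random.Generator:
    """Coerce ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def series_stream(master_seed: int, *labels) -> np.random.Generator:
    """Independent substream for one labelled series.

    The stream is keyed by a CRC32 of the labels (stable across processes,
    unlike ``hash()``), so adding or reordering series leaves every other
    series' draws unchanged.
    """
    key = zlib.crc32("|".join(str(l) for l in labels).encode("utf8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) % (2**31), spawn_key=(key,))
    return np.random.default_rng(ss)
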