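"""Named random sub-streams derived from one global seed.

Each generator component draws from its own stream so that adding or
reordering components never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``.

    The stream key is a CRC32 of the component name, so the mapping is
    stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
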