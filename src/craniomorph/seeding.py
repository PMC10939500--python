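"""Named random substreams.

All stochastic code in the package draws from `numpy.random.Generator`
instances produced by :func:`substream`, so a single user-supplied seed
determines every random quantity while independent stages (cohort noise,
permutation shuffles, droplet assignment, ...) consume statistically
independent streams that do not shift when an unrelated stage changes its
number of draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The stream name is hashed with CRC-32, which is stable across Python
    processes and platforms (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
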