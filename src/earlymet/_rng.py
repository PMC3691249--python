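"""Named, reproducible random substreams.

Every stochastic stage in the package draws from a substream derived from a
single master seed plus a tuple of string/int keys, so that changing the
bootstrap count of one stage never perturbs the randomness of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_ints(keys: tuple) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf-8")))
    return out


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator seeded by (seed, *keys); pure function of its inputs."""
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, *_key_ints(keys)])


def child_seed(seed: int, *keys) -> int:
    """A 31-bit integer seed for libraries that take plain int seeds."""
    return int(substream(seed, *keys).integers(2**31))
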