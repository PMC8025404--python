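"""Named random substreams derived from a single master seed.

Every stochastic operation in the package draws its generator from
:func:`substream`, so a run is fully determined by one integer seed while
independent operations (pool generation, gamete sampling, panel masking,
fold assignment, ...) never share or race for a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of stream names.

    Parameters
    ----------
    seed
        Master seed (any non-negative integer; reduced mod 2**31).
    *names
        Hashable path components, e.g. ``("cross", "F1", 3)``. The same
        path always yields the same stream; distinct paths are
        statistically independent.
    """
    keys = [zlib.crc32(str(n).encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *keys]))
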