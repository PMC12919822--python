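"""Named, independent random substreams derived from one root seed.

Every generator in the package draws from ``substream(seed, name)`` so that
adding a new generator (a new name) never perturbs the draws of existing
ones, and a fixed root seed gives byte-identical outputs.
"""

from __future__ import annotations

import random
import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a numpy Generator keyed by (seed, name)."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def py_substream(seed: int, name: str) -> random.Random:
    """Stdlib Random keyed by (seed, name), for libraries that need one."""
    return random.Random((int(seed) << 32) ^ zlib.crc32(name.encode()))
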