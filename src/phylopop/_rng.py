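"""Derivation of independent child RNG streams from one root seed.

Every stochastic operation in the package draws from a stream keyed by a
stable string (e.g. ``"reads/<sample_id>"``), so re-running one module in
isolation reproduces exactly the stream it saw inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(seed: int, key: str) -> np.random.Generator:
    """Return a Generator for (seed, key), independent across keys.

    The key is folded to a 32-bit word with CRC32 and combined with the
    root seed in a SeedSequence, which guarantees well-separated streams.
    """
    if not 0 <= seed < 2**31:
        raise ValueError(f"seed must be in [0, 2^31): got {seed}")
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(key.encode())]))
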