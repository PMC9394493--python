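"""Named random streams.

All randomness in the package flows from a single integer seed.  Each
sub-generator (baseline sampler, trajectory sampler, dropout draw, ...)
gets its own independent stream keyed by a stable name, so adding a new
stream never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return an independent :class:`numpy.random.Generator` for ``name``.

    The stream is derived from ``(seed, crc32(name))`` via
    :class:`numpy.random.SeedSequence`, so streams with different names are
    statistically independent and reproducible across runs and platforms.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=(key,)))
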