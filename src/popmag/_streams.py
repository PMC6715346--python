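"""Named, independent random-number streams.

Every stochastic component draws from a stream keyed by (seed, purpose,
index...), so regenerating one component (e.g. behavior) never shifts
another (e.g. spike counts).
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"stream keys must be nonnegative, got {key}")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"unsupported stream key type: {type(key)!r}")


def stream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Distinct key tuples give statistically independent streams; identical
    tuples give bit-identical streams.
    """
    entropy = [_key_to_int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
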