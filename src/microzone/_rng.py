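"""Named, reproducible random substreams.

Every stochastic stage of the simulator draws from its own generator, keyed
by the master seed plus a stage name and optional indices.  Results are then
independent of the order in which stages execute, and any single stage can
be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]

_MASK = 0x7FFFFFFF


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & _MASK
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf8")) & _MASK
    raise TypeError(f"substream keys must be int or str, got {type(key).__name__}")


def substream(master_seed: int, *keys: object) -> np.random.Generator:
    """Return a generator keyed by ``(master_seed, *keys)``.

    Keys may be integers (e.g. a rank index) or short strings (a stage
    name); strings are hashed with CRC-32 so the mapping is stable across
    sessions and platforms.
    """
    entropy = [_key_to_int(master_seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
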