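"""Hierarchical seeding.

Every random stream in a run is derived from one master seed plus a tuple of
string/int keys (stage name, year, flight, repeat...).  Adding a new stage with
a new key never perturbs the streams of existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def seed_sequence(master_seed: int, *keys: object) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``keys`` under ``master_seed``."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *map(_key_to_int, keys)])


def rng_for(master_seed: int, *keys: object) -> np.random.Generator:
    """Independent Generator for the stream identified by ``keys``."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))
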