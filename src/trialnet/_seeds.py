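"""Deterministic seed derivation.

All randomness in the package flows from a single master seed. Sub-streams
are derived with :class:`numpy.random.SeedSequence` keyed on the master seed
plus a stable integer hash of a string label (and optional integer indices),
so any artifact can be reproduced from the manifest alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "derive_rng", "spawn_seeds"]

_MOD = 2**31


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def child_seed(master_seed: int, label: str, *indices: int) -> int:
    """A reproducible integer seed (< 2**31) for the sub-stream ``label``."""
    ss = np.random.SeedSequence([int(master_seed), _label_key(label), *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % _MOD)


def derive_rng(master_seed: int, label: str, *indices: int) -> np.random.Generator:
    """A numpy Generator for the sub-stream ``label`` of ``master_seed``."""
    return np.random.default_rng(child_seed(master_seed, label, *indices))


def spawn_seeds(master_seed: int, label: str, n: int) -> list[int]:
    """``n`` distinct reproducible child seeds for indexed replicates."""
    return [child_seed(master_seed, label, i) for i in range(n)]
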