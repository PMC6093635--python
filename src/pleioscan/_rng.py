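"""Deterministic RNG streams keyed by string labels.

Every source of randomness in the package derives its generator from a
single master seed plus a tuple of labels, so results are independent of
execution order and reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stable_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator seeded from ``master_seed`` and hashed labels."""
    digest = hashlib.sha256("\x1f".join(str(x) for x in labels).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *words])
    return np.random.default_rng(seq)
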