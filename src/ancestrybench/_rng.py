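"""Named, order-independent random substreams.

Every stochastic operation in the package derives its generator from a root
seed plus a stable name, so the result of one operation can never depend on
how many random draws another operation made before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> tuple[int, ...]:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    # four 32-bit words are plenty of entropy for a spawn key
    return tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator unique to (seed, name) and independent of call order."""
    seq = np.random.SeedSequence(entropy=int(seed), spawn_key=_name_key(name))
    return np.random.default_rng(seq)
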