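"""Named, seed-derived random substreams.

All stochastic entry points accept one integer master seed; independent
module-level streams are derived from it by hashing a human-readable name
into the generator's seed material, so adding a new consumer never perturbs
existing streams.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_words(*names: str) -> list[int]:
    out = []
    for name in names:
        digest = hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest()
        out.append(int.from_bytes(digest, "little"))
    return out


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    return np.random.default_rng([int(seed), *_name_words(*names)])


def child_seed(seed: int, *names: str) -> int:
    """Derive a deterministic integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence([int(seed), *_name_words(*names)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
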