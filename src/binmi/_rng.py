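"""Named random-number streams.

All randomness in the package flows from a single user-supplied integer
seed.  Independent stages (cohort generation, methylation noise,
missingness, each bin x imputation) draw from *named* child streams so
that any stage can be reproduced in isolation and per-bin work can be
scheduled in any order without changing the output.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _label_key(label) -> int:
    """Map an arbitrary label to a stable 32-bit integer."""
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    digest = hashlib.sha256(str(label).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def stream(seed: int, *labels) -> np.random.Generator:
    """Return the generator for the child stream named by ``labels``.

    Streams with distinct labels are statistically independent; the same
    ``(seed, labels)`` pair always yields the same stream.
    """
    key = tuple(_label_key(lab) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def child_seed(seed: int, *labels) -> int:
    """Derive a deterministic integer seed (< 2**31) for a named sub-stage."""
    h = hashlib.sha256(repr((int(seed),) + tuple(str(l) for l in labels)).encode()).digest()
    return int.from_bytes(h[:4], "little") & 0x7FFFFFFF
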