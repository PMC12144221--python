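"""Named-substream random number generation.

All randomness in the synthetic study flows from a single top-level seed.
Each consumer (one scan, one reader/scan pair, ...) gets its own generator
derived from the seed plus a string key, so enlarging a design (adding doses
or repetitions) never perturbs the draws of scans that already existed.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a path of string-able keys.

    The key path is hashed (SHA-256) into the SeedSequence entropy, so the
    mapping key -> stream is stable across sessions and platforms and
    independent of the order in which substreams are created.
    """
    path = "/".join(str(k) for k in keys)
    digest = hashlib.sha256(path.encode("utf-8")).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32).tolist()
    ss = np.random.SeedSequence([int(seed)] + words)
    return np.random.default_rng(ss)
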