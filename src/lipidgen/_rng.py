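"""Named-stream random number generation.

Every stochastic component draws from its own generator, derived from one
integer seed plus a tuple of string labels (scenario, variable class, ...).
Streams with different labels are statistically independent, so adding a new
covariate or SNP to a scenario never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream_rng"]


def _label_key(label: object) -> int:
    digest = hashlib.blake2b(str(label).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def stream_rng(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the stream identified by ``labels``.

    Identical (seed, labels) always yields the same stream; any change to a
    label yields an independent stream.
    """
    key = tuple(_label_key(l) for l in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
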