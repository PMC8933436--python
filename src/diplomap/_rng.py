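"""Reproducible random-number substreams.

A single integer seed fans out to named substreams so that each simulation
stage (meiosis, phenotype noise, sequencing, ...) draws from an independent
generator and can be re-run in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``seed``.

    The mapping is stable across sessions and platforms: the stream key is
    derived from a SHA-256 digest of ``"{seed}:{name}"``.
    """
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    key = int.from_bytes(digest[:16], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
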