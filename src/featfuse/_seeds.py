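"""Deterministic seed substreams.

Every stage draws its randomness from a named substream of one master seed so
stages can be re-run independently and whole experiments are reproducible from
a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def substream_seed(master_seed: int, *names: object) -> int:
    """Derive a stable integer seed (< 2^31) for a named substream.

    The derivation hashes the master seed together with the stream names, so
    ``substream_seed(s, "split")`` and ``substream_seed(s, "elm", 3)`` are
    independent yet reproducible.
    """
    key = ":".join([str(int(master_seed))] + [str(n) for n in names])
    digest = zlib.crc32(key.encode("utf-8"))
    mixed = np.random.SeedSequence([int(master_seed) % _MOD, digest]).generate_state(1)[0]
    return int(mixed % _MOD)


def rng_for(master_seed: int, *names: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded from a named substream."""
    return np.random.default_rng(substream_seed(master_seed, *names))
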