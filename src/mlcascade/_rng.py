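"""Seed plumbing: named, reproducible substreams from a single user seed."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed for the named component."""
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
               .generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(seed: int | None, name: str) -> np.random.Generator:
    """A generator for the named substream.

    Distinct names give independent streams; the same (seed, name) pair always
    yields the same stream, so adding one analysis never perturbs the draws of
    another.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(child_seed(seed, name))
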