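"""Deterministic child-seed derivation.

All stochastic operations in the package derive their random state from a
single integer master seed through :func:`child_seed`, replacing any
clock-based randomisation. Tags (strings or integers) namespace the child
streams so that, e.g., the FTO draws of list 3 / trial 7 never collide with
those of list 3 / trial 8.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def child_seed(master_seed: int, *tags: object) -> int:
    """Derive a reproducible child seed (< 2**31) from ``master_seed`` and tags."""
    ss = np.random.SeedSequence([int(master_seed)] + [_tag_to_int(t) for t in tags])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, *tags: object) -> np.random.Generator:
    """A numpy Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *tags))
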