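"""Hierarchical seed derivation.

A single integer seed drives the whole pipeline.  Each generator derives its
own independent stream from (master seed, label) so that stages can be
regenerated in isolation without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, label: str) -> np.random.SeedSequence:
    """Return a SeedSequence for ``label`` under ``master_seed``.

    The label is hashed with CRC-32, so derivation is stable across runs and
    Python processes (unlike ``hash``).
    """
    if not isinstance(master_seed, (int, np.integer)) or master_seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {master_seed!r}")
    return np.random.SeedSequence(int(master_seed), spawn_key=(zlib.crc32(label.encode("utf-8")),))


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` dedicated to one named stream."""
    return np.random.default_rng(derive_seed(master_seed, label))
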