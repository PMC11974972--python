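"""Seed-stream discipline: one root seed, labelled child streams.

Every stochastic operation in the package draws from a child generator
derived from a root seed and a fixed string label, so runs are bit-identical
for identical seeds and independent operations never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_entropy(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def child_seed(root_seed: int, label: str) -> int:
    """A deterministic 31-bit child seed for ``label`` under ``root_seed``."""
    ss = np.random.SeedSequence([int(root_seed), _label_entropy(label)])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """Generator for the (root_seed, label) stream."""
    ss = np.random.SeedSequence([int(root_seed), _label_entropy(label)])
    return np.random.default_rng(ss)
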