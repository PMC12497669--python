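"""Seed plumbing: one master seed, named independent streams.

Every stochastic routine draws from a stream derived from the master seed
and a tuple of labels (dataset index, start index, repeat index, ...), so
changing e.g. the number of fit starts never perturbs the noise realisation
of a dataset.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_stream", "stream_seed"]


def _label_key(labels) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)


def rng_stream(seed: int, *labels) -> np.random.Generator:
    """Generator for the stream named by ``labels`` under ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_label_key(labels))
    return np.random.default_rng(ss)


def stream_seed(seed: int, *labels) -> int:
    """A 31-bit integer seed for the named stream (for APIs wanting ints)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_label_key(labels))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
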