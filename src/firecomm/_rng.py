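"""Seed plumbing: one global seed expands to per-stage substreams.

Every stochastic stage draws from ``stage_rng(seed, stage_name)`` so that
stage-level reruns are reproducible independently of the other stages.
"""

from __future__ import annotations

import zlib

import numpy as np

# Fixed, documented offsets; names are stable API.
_STAGE_OFFSETS = {
    "design": 1,
    "counts": 2,
    "esv_weights": 3,
    "index_reads": 4,
    "barcodes": 5,
    "permutation": 6,
    "contrasts": 7,
    "simulation": 8,
}


def stage_offset(stage: str) -> int:
    """Stable small-integer offset for a stage name."""
    if stage in _STAGE_OFFSETS:
        return _STAGE_OFFSETS[stage]
    return int(zlib.crc32(stage.encode())) % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for one named substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), stage_offset(stage))))
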