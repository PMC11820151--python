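"""Per-tag, per-stage random number streams.

Each (seed, tag_id, stage) triple maps to an independent numpy Generator so
that adding tags or stages to a simulation never perturbs the draws of
existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_stream", "tag_key"]


def tag_key(tag_id: object) -> int:
    """Stable 32-bit key for a tag identifier (int or string)."""
    if isinstance(tag_id, (int, np.integer)):
        return int(tag_id) & 0xFFFFFFFF
    return zlib.crc32(str(tag_id).encode("utf-8"))


def rng_stream(seed: int, tag_id: object, stage: str) -> np.random.Generator:
    """Independent Generator for one tag and one simulation stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag_key(tag_id), zlib.crc32(stage.encode())])
    )
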