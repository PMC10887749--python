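"""Seed-stream plumbing: one root seed fans out into named substreams."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Streams for distinct names are statistically independent (distinct
    SeedSequence spawn keys), and regenerating one stage of a pipeline does
    not perturb the draws of any other stage.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
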