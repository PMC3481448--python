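"""Named RNG substreams.

Every stochastic stage of the pipeline draws from its own substream derived
from (seed, stage name), so changing the number of draws in one stage never
perturbs another stage's stream. The mapping from name to spawn key is stable
and part of the public determinism contract.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "subseed"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` deterministically derived from ``seed``.

    The stage name is hashed with crc32 (stable across processes and Python
    versions, unlike ``hash``) and combined with the seed in a SeedSequence.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def subseed(seed: int, tag: str) -> int:
    """A deterministic sub-seed for a tagged purpose (e.g. train vs test draws).

    Keeps composed stages on disjoint streams even when they share stage
    names internally. Result is a non-negative 31-bit integer.
    """
    return (int(seed) ^ zlib.crc32(tag.encode("utf-8"))) & 0x7FFFFFFF
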