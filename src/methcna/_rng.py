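"""Seed plumbing: one root seed, named per-stage child streams.

Each analysis stage draws from a generator derived from the root seed and
the stage name, so rerunning a single stage reproduces its randomness
without replaying earlier stages.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def _name_key(name: str) -> int:
    # stable across processes/platforms, unlike hash()
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def stage_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Seed sequence for a named stage under a root seed."""
    return np.random.SeedSequence([int(seed), _name_key(name)])


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Generator for a named stage (e.g. ``stage_rng(7, "global_test")``)."""
    return np.random.default_rng(stage_seed(seed, name))
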