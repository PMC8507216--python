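"""Shared helpers: seeding, hashing, validation."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np

# Default master seed used by every stochastic stage unless overridden.
DEFAULT_SEED = 20210123


def rng_from(seed: int | None, *tokens) -> np.random.Generator:
    """Build a Generator from a base seed plus stable string/int tokens.

    Tokens let independent stages (cohort draw, each phantom, each fold
    shuffle) derive decorrelated streams from one master seed without
    consuming state from a shared generator.
    """
    if seed is None:
        seed = DEFAULT_SEED
    words = [int(seed) & 0xFFFFFFFF]
    for t in tokens:
        if isinstance(t, (int, np.integer)):
            words.append(int(t) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(t).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(words))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def check_positive(name: str, value) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def check_in_unit_interval(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
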