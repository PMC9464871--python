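"""Shared helpers: deterministic seed derivation and rounding rules."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed", "round_half_up"]


def _key_bytes(keys: tuple) -> bytes:
    parts = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            parts.append(b"i" + int(k).to_bytes(16, "little", signed=True))
        elif isinstance(k, str):
            parts.append(b"s" + k.encode("utf-8"))
        elif isinstance(k, float):
            parts.append(b"f" + repr(float(k)).encode("ascii"))
        else:
            raise TypeError(f"unsupported seed key type: {type(k)!r}")
        parts.append(b"\x00")
    return b"".join(parts)


def derive_seed(*keys) -> int:
    """Derive a stable 31-bit seed from a tuple of ints/strings/floats.

    Uses SHA-256 so that nearby experiment seeds (e.g. seed and seed+1 with
    different repeat indices) can never collide into the same stream.
    """
    digest = hashlib.sha256(_key_bytes(keys)).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def derive_rng(*keys) -> np.random.Generator:
    """A numpy Generator keyed by an arbitrary tuple of ints/strings/floats."""
    digest = hashlib.sha256(_key_bytes(keys)).digest()
    words = np.frombuffer(digest, dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence(words.tolist()))


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero toward +inf (⌊x⌉)."""
    return int(np.floor(x + 0.5))
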