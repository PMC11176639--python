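"""Deterministic seed derivation shared across the package.

Every stochastic routine takes an integer seed and derives independent
sub-streams from it with :func:`derive_seed`, so that reordering inputs or
toggling pipeline stages never shifts another computation's random stream.
"""
from __future__ import annotations

import zlib

__all__ = ["derive_seed"]


def derive_seed(base: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from ``base`` and identifying tokens.

    Tokens are hashed by their string representation, so identifiers (sample
    ids, stage names) give order-independent, stable streams.
    """
    h = zlib.crc32(repr(tuple(str(t) for t in tokens)).encode("utf-8"))
    return (int(base) ^ h) & 0x7FFFFFFF
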