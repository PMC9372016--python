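"""Shared helpers: deterministic sub-seeding and error types."""

from __future__ import annotations

import hashlib


class ScshiftError(Exception):
    """Base class for all package errors."""


class FormatError(ScshiftError):
    """Raised when an input file violates its declared format."""


class EmptyAfterQCError(ScshiftError):
    """Raised when quality filtering removes every cell."""


def stable_seed(master_seed: int, *tokens: object) -> int:
    """Derive a reproducible sub-seed from a master seed and context tokens.

    Independent of execution order: the sub-stream for (stage, stratum,
    cell type) is a pure function of the master seed and those tokens.
    Result is always < 2**31 so it is safe for any RNG constructor.
    """
    key = "|".join([str(master_seed), *map(str, tokens)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
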