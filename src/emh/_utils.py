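"""Shared helpers: error types, seed derivation, logging."""

from __future__ import annotations

import logging
import zlib

logger = logging.getLogger("emh")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when an on-disk file does not conform to its format."""


def derive_seed(base_seed: int, *labels: str) -> int:
    """Derive a child seed from a base seed and one or more string labels.

    Uses CRC32 of the joined labels so the same (seed, labels) pair always
    yields the same child seed, independent of process hash randomization.
    The result is kept below 2**31.
    """
    tag = zlib.crc32("/".join(labels).encode("utf-8"))
    return (int(base_seed) * 2654435761 + tag) % (2**31 - 1)
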