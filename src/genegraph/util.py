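"""Small shared utilities: deterministic hashing and error types."""

from __future__ import annotations

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


def fnv1a64(name: str) -> int:
    """64-bit FNV-1a hash of a name's UTF-8 bytes.

    Used everywhere a tie between equally scored genes or proteins must be
    broken deterministically: the candidate with the smaller hash wins.
    """
    h = _FNV_OFFSET
    for b in name.encode("utf-8"):
        h ^= b
        h = (h * _FNV_PRIME) & _MASK64
    return h


class GeneGraphError(Exception):
    """Base class for all errors raised by this package."""


class MissingEdgeError(GeneGraphError):
    """Raised when an adjacency is queried that is not present in the graph."""


class DuplicateWalkError(GeneGraphError):
    """Raised when a second walk is registered for the same contig."""


class GFAParseError(GeneGraphError):
    """Raised on malformed GFA input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GFAValidationError(GeneGraphError):
    """Raised when GFA walk lines are inconsistent with the link lines."""


class PAFParseError(GeneGraphError):
    """Raised on malformed alignment input."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigError(GeneGraphError):
    """Raised for contradictory or invalid configuration."""
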