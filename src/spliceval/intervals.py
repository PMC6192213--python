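"""Genomic interval primitives.

Every coordinate in this package is 0-based, half-open ``[start, end)`` on a
named sequence. Source formats that use other conventions (GTF: 1-based
inclusive; SAM POS: 1-based) are converted at parse time, never downstream.
"""

from __future__ import annotations

from dataclasses import dataclass


class SplicevalError(Exception):
    """Base class for all package errors."""


class ParseError(SplicevalError):
    """An input file violates its format contract."""


class ContractError(SplicevalError):
    """A function was called with arguments violating its precondition."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    Invariant: ``0 <= start < end`` (zero-length intervals are rejected).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ContractError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if on different sequences)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))
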