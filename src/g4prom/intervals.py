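"""Genomic interval primitives and coordinate-convention converters.

Internal coordinates are always 0-based half-open ``[start, end)`` on a named
chromosome, the BED convention.  GTF and CTSS files are 1-based inclusive;
every conversion between the two conventions passes through the audited
functions in this module so that off-by-one errors have a single place to
hide (and be tested).
"""

from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        """True iff the two intervals share >= 1 base (half-open arithmetic)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


def one_based_span_to_zero(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span (GTF) to 0-based half-open (internal).

    GTF exon [101, 200] (1-based, inclusive) becomes internal [100, 200).
    """
    if start1 < 1 or end1 < start1:
        raise ValueError(f"invalid 1-based span [{start1}, {end1}]")
    return start1 - 1, end1


def zero_span_to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open span (internal/BED) to 1-based inclusive."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based span [{start0}, {end0})")
    return start0 + 1, end0


def one_based_pos_to_interval(pos1: int) -> tuple[int, int]:
    """A single 1-based position (CTSS) occupies internal interval [pos-1, pos)."""
    if pos1 < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos1}")
    return pos1 - 1, pos1
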