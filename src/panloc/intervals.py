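"""Genomic interval primitives shared across the package.

All coordinates inside the library are 0-based half-open (the PAF/BED
convention). Region strings typed on a command line follow the samtools
convention (1-based, fully closed, e.g. ``6:69000000-71000000``); they are
converted exactly once, at the boundary, by :func:`parse_region`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GenomicInterval", "interval_length", "parse_region"]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start <= end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )

    def __str__(self) -> str:  # 0-based half-open, BED-like
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp of a half-open interval: ``end - start``."""
    return interval.end - interval.start


def parse_region(region: str) -> GenomicInterval:
    """Parse a samtools-style region string into a 0-based half-open interval.

    ``"chr6:69000000-71000000"`` (1-based, inclusive) becomes
    ``GenomicInterval("chr6", 68999999, 71000000)``. Thousands separators
    (commas) are tolerated. A bare sequence name is rejected because the
    callers of this function always need an explicit span.
    """
    if ":" not in region:
        raise ValueError(f"region {region!r} lacks a ':start-end' span")
    chrom, _, span = region.rpartition(":")
    span = span.replace(",", "")
    lo, sep, hi = span.partition("-")
    if not sep or not lo or not hi:
        raise ValueError(f"region {region!r}: span must be 'start-end'")
    try:
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise ValueError(f"region {region!r}: non-integer bound") from exc
    if start1 < 1 or end1 < start1:
        raise ValueError(f"region {region!r}: require 1 <= start <= end")
    return GenomicInterval(chrom, start1 - 1, end1)
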