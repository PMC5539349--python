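"""Genomic interval primitives.

All internal coordinates are 0-based, half-open ``[start, end)``.  File
formats with 1-based coordinates (cytosine reports, SNP tables) are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def distance_to_point(self, chrom: str, pos: int) -> int | None:
        """Distance from the nearest edge of the interval to ``pos``; 0 if inside.

        Returns None for a different chromosome.
        """
        if chrom != self.chrom:
            return None
        if self.start <= pos < self.end:
            return 0
        if pos < self.start:
            return self.start - pos
        return pos - (self.end - 1)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping intervals (book-ended, touching ones stay separate).

    Idempotent and independent of input order.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def any_overlap(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)
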