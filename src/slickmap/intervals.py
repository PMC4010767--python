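"""Genomic interval arithmetic.

All intervals are 1-based with both endpoints inclusive, matching the physical
SNP coordinates used throughout the package. The *span* of an interval is
defined as ``end_bp - start_bp`` — i.e. the distance between the first and last
base rather than the number of bases covered — because that is the convention
used for haplotype-block distances in the pattern tables this package emits and
parses.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed interval on a chromosome."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"start_bp must be >= 1, got {self.start_bp}")
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"end_bp ({self.end_bp}) < start_bp ({self.start_bp})"
            )

    @property
    def span_bp(self) -> int:
        """Distance end - start (excludes the first base by construction)."""
        return self.end_bp - self.start_bp

    @property
    def span_mb(self) -> float:
        return self.span_bp / 1e6

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


def span(iv: GenomicInterval) -> int:
    """Block distance in bp: ``end_bp - start_bp``."""
    return iv.span_bp


def intersect(intervals: list[GenomicInterval]) -> GenomicInterval | None:
    """Intersection of intervals on one chromosome; ``None`` when empty.

    Raises
    ------
    ValueError
        If the list is empty or mixes chromosomes.
    """
    if not intervals:
        raise ValueError("intersect() requires at least one interval")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot intersect intervals across chromosomes: {sorted(chroms)}")
    start = max(iv.start_bp for iv in intervals)
    end = min(iv.end_bp for iv in intervals)
    if start > end:
        return None
    return GenomicInterval(intervals[0].chrom, start, end)


def merge_overlapping(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals (single chromosome).

    Intervals that share even a single base (closed-coordinate overlap) are
    merged; abutting intervals (end+1 == next start) are kept separate.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError("merge_overlapping() requires a single chromosome")
    ivs = sorted(intervals, key=lambda iv: (iv.start_bp, iv.end_bp))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start_bp <= last.end_bp:
            if iv.end_bp > last.end_bp:
                merged[-1] = GenomicInterval(last.chrom, last.start_bp, iv.end_bp)
        else:
            merged.append(iv)
    return merged


def to_bed_line(iv: GenomicInterval, name: str = ".", score: float | None = None) -> str:
    """Serialize to a BED record (0-based half-open conversion done here)."""
    fields = [iv.chrom, str(iv.start_bp - 1), str(iv.end_bp), name]
    if score is not None:
        fields.append(f"{score:g}")
    return "\t".join(fields)


def from_bed_line(line: str) -> GenomicInterval:
    """Parse a BED record into a 1-based closed interval."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"malformed BED line: {line!r}")
    return GenomicInterval(fields[0], int(fields[1]) + 1, int(fields[2]))
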