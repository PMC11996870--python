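"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based coordinate (genome-browser style) is converted at the
boundary and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``name`` and ``score`` are optional annotations (BED columns 4 and 5);
    they do not participate in overlap arithmetic.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus a signal attribution.

    ``signal`` is whatever pileup/enrichment quantity the peak caller
    emitted (for narrowPeak input, the signalValue column by default).
    """

    interval: GenomicInterval
    signal: float
    name: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name}: signal must be >= 0")


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: a gene id anchored at a single base."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"{self.gene_id}: TSS pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base.

    Book-ended intervals ([0,100) and [100,200)) do NOT overlap.
    """
    return overlap_bp(a, b) > 0


def point_interval_distance(pos: int, iv: GenomicInterval) -> int:
    """Distance in bp from a point to an interval.

    Zero when the point lies inside ``[start, end)``; otherwise the distance
    to the nearest contained base, i.e. min(|pos - start|, |pos - (end-1)|).
    """
    if iv.start <= pos < iv.end:
        return 0
    return min(abs(pos - iv.start), abs(pos - (iv.end - 1)))


def filter_blacklist(
    peaks: list[Peak], blacklist: list[GenomicInterval]
) -> list[Peak]:
    """Drop peaks overlapping any blacklist interval by >= 1 bp.

    Any overlap removes the peak (no reciprocal-fraction rule), matching
    common ENCODE-blacklist practice.  Input order is preserved.
    """
    if not blacklist:
        return list(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in blacklist:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda x: x.start)
    kept = []
    for p in peaks:
        hits = by_chrom.get(p.interval.chrom, ())
        if not any(overlaps(p.interval, b) for b in hits):
            kept.append(p)
    return kept


def merge_intervals(
    intervals: list[GenomicInterval], max_gap: int = 0
) -> list[list[GenomicInterval]]:
    """Group intervals transitively whenever the gap between neighbours on
    the same chromosome is <= ``max_gap``.

    With ``max_gap=0`` overlapping or book-ended intervals merge; larger
    values implement stitching.  Returns groups of the input intervals in
    (chrom, start) order.
    """
    groups: list[list[GenomicInterval]] = []
    current: list[GenomicInterval] = []
    current_end = 0
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if current and iv.chrom == current[0].chrom and iv.start - current_end <= max_gap:
            current.append(iv)
            current_end = max(current_end, iv.end)
        else:
            if current:
                groups.append(current)
            current = [iv]
            current_end = iv.end
    if current:
        groups.append(current)
    return groups


def span(intervals: list[GenomicInterval], name: str | None = None) -> GenomicInterval:
    """The enclosing interval min(start)..max(end) of a non-empty group."""
    if not intervals:
        raise ValueError("cannot take span of an empty group")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"span across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
        name=name,
    )
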