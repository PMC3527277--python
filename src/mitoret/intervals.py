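"""Genomic interval data model and overlap primitives.

Coordinates are 0-based, half-open (BED convention) throughout the
package; any 1-based dialect must be converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of intervals, optionally bound to a genome.

    Intervals are normalized on construction: sorted by
    (chrom lexicographic, start, end) and, when a genome map is present,
    clipped to chromosome bounds (clipping is logged, not an error).
    Unknown chromosomes under a genome map are a validation error.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: dict[str, int] | None = None,
    ) -> None:
        self.genome = dict(genome) if genome else None
        ivs = list(intervals)
        if self.genome is not None:
            ivs = [self._validate_and_clip(iv) for iv in ivs]
        self.intervals: list[GenomicInterval] = sorted(
            ivs, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def _validate_and_clip(self, iv: GenomicInterval) -> GenomicInterval:
        assert self.genome is not None
        if iv.chrom not in self.genome:
            raise ValueError(f"chromosome {iv.chrom!r} not in genome map")
        limit = self.genome[iv.chrom]
        if iv.end > limit:
            logger.info(
                "clipping interval %s:%d-%d to chromosome end %d",
                iv.chrom, iv.start, iv.end, limit,
            )
            iv = replace(iv, end=limit)
        return iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def total_bp(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def filter_chromosomes(self, drop: Sequence[str]) -> "IntervalSet":
        """Remove every interval on a chromosome in ``drop``.

        Dropping absent chromosomes is a no-op.  Used to discard peaks
        on unassembled scaffolds (e.g. chrU / chrUextra).
        """
        dropset = set(drop)
        kept = [iv for iv in self.intervals if iv.chrom not in dropset]
        genome = (
            {c: l for c, l in self.genome.items() if c not in dropset}
            if self.genome
            else None
        )
        return IntervalSet(kept, genome=genome)

    def merged(self) -> "IntervalSet":
        """Union of all intervals: overlapping or adjacent runs collapsed."""
        out: list[GenomicInterval] = []
        for iv in self.intervals:
            if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
                prev = out[-1]
                if iv.end > prev.end:
                    out[-1] = replace(prev, end=iv.end)
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(out, genome=self.genome)


@dataclass
class ReadSet:
    """Single-end read 5' positions with strand.

    ``total_mapped`` is the sequencing-depth denominator for RPM
    normalization; it may exceed the number of stored reads (e.g. after
    restricting to regions of interest).
    """

    reads: list[tuple[str, int, str]] = field(default_factory=list)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.total_mapped < len(self.reads):
            raise ValueError(
                "total_mapped must be >= number of stored reads "
                f"({self.total_mapped} < {len(self.reads)})"
            )

    def __len__(self) -> int:
        return len(self.reads)


def build_trees(s: IntervalSet) -> dict[str, IntervalTree]:
    """Index an IntervalSet as per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(s):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def overlap_pairs(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> tuple[list[tuple[int, int]], int]:
    """All (a-index, b-index) pairs whose intersection is >= min_bp.

    Returns the sorted pair list and the number of distinct a-intervals
    with at least one partner.  Overlap requires at least one shared
    base pair by default.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    trees = build_trees(b)
    pairs: list[tuple[int, int]] = []
    hit_a: set[int] = set()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for node in tree.overlap(iv.start, iv.end):
            inter = min(iv.end, node.end) - max(iv.start, node.begin)
            if inter >= min_bp:
                pairs.append((i, node.data))
                hit_a.add(i)
    pairs.sort()
    return pairs, len(hit_a)


def count_overlapping(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> int:
    """Number of a-intervals overlapping at least one b-interval."""
    _, count = overlap_pairs(a, b, min_bp=min_bp)
    return count
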