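"""Genomic intervals and the small interval algebra used across the pipeline.

All coordinates are 0-based half-open internally; file readers convert
1-based inclusive dialects (PURPLE-like TSV) at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Self-merge an interval set: sort, then coalesce touching/overlapping runs."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered after self-merging."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersection_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """bp covered by both sets (each self-merged first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    n = 0
    for iv in ma:
        for jv in mb:
            n += iv.overlap_length(jv)
    return n


def overlap_any(
    query: GenomicInterval, targets: Sequence[GenomicInterval], min_overlap: int = 1
) -> bool:
    """True if query overlaps any target by at least ``min_overlap`` bp."""
    return any(query.overlap_length(t) >= min_overlap for t in targets)
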