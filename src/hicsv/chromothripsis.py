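"""Sliding-window chromothripsis caller.

A 2.5 Mb window is slid at 10 kb steps along each chromosome; a window is
called chromothriptic when it simultaneously contains at least 15 inversion
breakpoints, 15 copy-number switches, and 10 deletion breakpoints. A
chromosome is positive when any window is called; overlapping called windows
are merged into regions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, merge_intervals
from .stats import TestResult, fisher_exact_2x2
from .variants import AmpliconEvent, Breakpoint, CopyNumberSegmentSet


@dataclass
class ChromothripsisConfig:
    window_size: int = 2_500_000
    step: int = 10_000
    min_inversions: int = 15
    min_cn_switches: int = 15
    min_deletions: int = 10
    switch_epsilon: float = 0.5  # |dCN| for an adjacent boundary to count

    def __post_init__(self) -> None:
        if min(self.window_size, self.step, self.min_inversions,
               self.min_cn_switches, self.min_deletions) <= 0:
            raise ValueError("config values must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


@dataclass
class WindowCounts:
    window: GenomicInterval
    n_inversions: int
    n_deletions: int
    n_cn_switches: int
    called: bool


def _switch_positions(segments: CopyNumberSegmentSet, chrom: str,
                      eps: float) -> np.ndarray:
    """Positions of adjacent-segment boundaries where CN jumps by > eps."""
    segs = segments.on_chrom(chrom)
    pos = []
    for a, b in zip(segs, segs[1:]):
        if abs(b.copy_number - a.copy_number) > eps:
            pos.append(a.interval.end)
    return np.asarray(sorted(pos), dtype=int)


def count_window_features(
    breakpoints: list[Breakpoint],
    segments: CopyNumberSegmentSet,
    chrom: str,
    chrom_length: int,
    config: ChromothripsisConfig | None = None,
) -> list[WindowCounts]:
    """Per-window inversion / deletion / CN-switch counts along a chromosome.

    An SV counts only if BOTH breakends lie inside the window (intra-
    chromosomal SVs only, by construction).
    """
    config = config or ChromothripsisConfig()

    def _ends(sv_type: str) -> np.ndarray:
        out = [
            (b.pos1, b.pos2) for b in breakpoints
            if b.sv_type == sv_type and b.chrom1 == chrom and b.chrom2 == chrom
        ]
        return np.asarray(sorted(out), dtype=int).reshape(-1, 2)

    inv, dele = _ends("INV"), _ends("DEL")
    switches = _switch_positions(segments, chrom, config.switch_epsilon)

    counts = []
    last_start = max(0, chrom_length - config.window_size)
    starts = np.arange(0, last_start + 1, config.step)
    if len(starts) == 0 or starts[-1] < last_start:
        starts = np.append(starts, last_start)
    for ws in starts:
        we = min(ws + config.window_size, chrom_length)
        n_inv = int(((inv[:, 0] >= ws) & (inv[:, 1] < we)).sum()) if inv.size else 0
        n_del = int(((dele[:, 0] >= ws) & (dele[:, 1] < we)).sum()) if dele.size else 0
        n_sw = int(((switches >= ws) & (switches < we)).sum()) if switches.size else 0
        called = (
            n_inv >= config.min_inversions
            and n_sw >= config.min_cn_switches
            and n_del >= config.min_deletions
        )
        counts.append(
            WindowCounts(GenomicInterval(chrom, int(ws), int(we)),
                         n_inv, n_del, n_sw, called)
        )
    return counts


def call_chromothripsis(
    window_counts: dict[str, list[WindowCounts]]
) -> tuple[dict[str, bool], list[GenomicInterval]]:
    """Per-chromosome verdicts plus merged called regions."""
    verdict = {}
    called_windows = []
    for chrom, counts in window_counts.items():
        hit = [w.window for w in counts if w.called]
        verdict[chrom] = bool(hit)
        called_windows.extend(hit)
    return verdict, merge_intervals(called_windows)


def csv_chromothripsis_association(
    events_by_sample: dict[str, list[AmpliconEvent]],
    chromothripsis_calls: dict[tuple[str, str], bool],
) -> TestResult:
    """Fisher's exact association between {ecDNA/BFB on chromosome} and
    {chromothripsis on chromosome} over all (sample, chromosome) pairs."""
    if not chromothripsis_calls:
        raise ValueError("empty cohort")
    csv_chroms: set[tuple[str, str]] = set()
    for sample, events in events_by_sample.items():
        for ev in events:
            if ev.event_class in ("ecDNA", "BFB"):
                for c in ev.chromosomes:
                    csv_chroms.add((sample, c))
    table = np.zeros((2, 2), dtype=int)
    for key, ct in chromothripsis_calls.items():
        has_csv = key in csv_chroms
        table[0 if has_csv else 1][0 if ct else 1] += 1
    return fisher_exact_2x2(table)
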