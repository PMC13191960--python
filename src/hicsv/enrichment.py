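"""Regulatory-element overlap annotation and the randomization test for
enrichment of cSV segments in peak regions (H3K27ac, super-enhancers).

Each permutation re-places every query interval uniformly at random on its
own chromosome within mask-free space (the ENCODE exclusion list), preserving
interval length and chromosome distribution; the statistic is the number of
query intervals overlapping at least one peak.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, merge_intervals, overlap_any
from .variants import AmpliconEvent

MIN_OVERLAP_BP = 100  # annotation rule: positive iff >= 100 bp peak overlap


@dataclass
class PermutationResult:
    observed_overlap_count: int
    null_counts: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int


def annotate_overlap(
    events: list[AmpliconEvent],
    peaks: list[GenomicInterval],
    min_overlap_bp: int = MIN_OVERLAP_BP,
) -> tuple[dict[str, bool], dict[str, float]]:
    """Per-event positivity (any segment overlaps a peak by >= min_overlap_bp)
    and positive fractions by event class."""
    merged = merge_intervals(peaks)
    flags: dict[str, bool] = {}
    by_class: dict[str, list[bool]] = {}
    for ev in events:
        pos = any(
            overlap_any(iv, merged, min_overlap=min_overlap_bp)
            for iv in ev.intervals
        )
        flags[f"{ev.sample_id}:{ev.event_id}"] = pos
        by_class.setdefault(ev.event_class, []).append(pos)
    fractions = {c: float(np.mean(v)) for c, v in sorted(by_class.items())}
    return flags, fractions


def _free_gaps(chrom_len: int, mask: list[GenomicInterval]) -> list[tuple[int, int]]:
    gaps = []
    pos = 0
    for iv in merge_intervals(mask):
        if iv.start > pos:
            gaps.append((pos, iv.start))
        pos = max(pos, iv.end)
    if pos < chrom_len:
        gaps.append((pos, chrom_len))
    return gaps


def _sample_start(gaps: list[tuple[int, int]], length: int,
                  rng: np.random.Generator) -> int:
    """Uniform start over all mask-free placements of an interval of
    ``length`` bp (exact gap-sampling)."""
    sizes = np.array([max(0, (e - s) - length + 1) for s, e in gaps])
    total = sizes.sum()
    if total <= 0:
        raise ValueError(
            f"interval of {length} bp does not fit in any mask-free gap"
        )
    u = int(rng.integers(total))
    for (s, _), k in zip(gaps, sizes):
        if u < k:
            return s + u
        u -= k
    raise AssertionError("unreachable")


def permutation_overlap_test(
    query_intervals: list[GenomicInterval],
    peaks: list[GenomicInterval],
    genome: dict[str, int],
    exclusion_mask: list[GenomicInterval] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    _check_mask: bool = False,
) -> PermutationResult:
    """Permutation enrichment test of query intervals against peaks.

    empirical_p = (1 + #{null >= observed}) / (n_perm + 1); deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    exclusion_mask = exclusion_mask or []
    mask_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusion_mask:
        mask_by_chrom.setdefault(iv.chrom, []).append(iv)
    gaps = {
        c: _free_gaps(genome[c], mask_by_chrom.get(c, []))
        for c in genome
    }
    # merged, sorted peak arrays per chromosome for any-overlap lookups
    peak_lists: dict[str, tuple[list[int], list[int]]] = {}
    for iv in merge_intervals(peaks):
        s, e = peak_lists.setdefault(iv.chrom, ([], []))
        s.append(iv.start)
        e.append(iv.end)
    peak_arr = {c: (np.array(s), np.array(e)) for c, (s, e) in peak_lists.items()}

    def _hit_mask(chrom: str, starts: np.ndarray, length: int) -> np.ndarray:
        """For merged non-overlapping peaks: query [s, s+L) overlaps a peak
        iff the first peak ending after s starts before s+L."""
        if chrom not in peak_arr:
            return np.zeros(len(starts), dtype=bool)
        ps, pe = peak_arr[chrom]
        idx = np.searchsorted(pe, starts, side="right")
        ok = idx < len(ps)
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = ps[idx[ok]] < starts[ok] + length
        return out

    observed = 0
    null_hits = np.zeros(n_perm, dtype=int)
    for iv in query_intervals:
        length = len(iv)
        chrom_gaps = gaps[iv.chrom]
        sizes = np.array(
            [max(0, (e - s) - length + 1) for s, e in chrom_gaps], dtype=np.int64
        )
        total = sizes.sum()
        if total <= 0:
            raise ValueError(
                f"interval of {length} bp does not fit in any mask-free gap "
                f"on {iv.chrom}"
            )
        observed += int(_hit_mask(iv.chrom, np.array([iv.start]), length)[0])
        u = rng.integers(total, size=n_perm)
        cum = np.cumsum(sizes)
        gap_idx = np.searchsorted(cum, u, side="right")
        gap_starts = np.array([s for s, _ in chrom_gaps])
        offset = u - (cum[gap_idx] - sizes[gap_idx])
        starts = gap_starts[gap_idx] + offset
        if _check_mask:
            for s in starts[: min(50, n_perm)]:
                riv = GenomicInterval(iv.chrom, int(s), int(s) + length)
                assert not overlap_any(riv, mask_by_chrom.get(iv.chrom, []))
        null_hits += _hit_mask(iv.chrom, starts, length)
    p_emp = (1 + int((null_hits >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed, null_hits, p_emp, n_perm, seed)
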