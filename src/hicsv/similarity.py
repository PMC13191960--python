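"""Cross-sample cSV similarity: do two amplifications of the same locus
derive from one event (shared origin) or arise independently (convergence)?

Two complementary measures: a genomic-footprint Jaccard over merged
intervals, and a breakpoint Jaccard index over junctions matched one-to-one
within a positional tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, intersection_length, merge_intervals, total_length
from .variants import AmpliconEvent, Breakpoint

TOL_BP_DEFAULT = 100
THETA_SHARED = 0.25
THETA_INDEPENDENT = 0.05


@dataclass(frozen=True)
class SimilarityScore:
    event_a: str
    event_b: str
    interval_jaccard: float
    breakpoint_jaccard: float
    n_matched_breakpoints: int
    verdict: str  # shared / independent / indeterminate


def interval_jaccard(a: list[GenomicInterval], b: list[GenomicInterval]) -> float:
    """bp(A intersect B) / bp(A union B), each set self-merged first."""
    if not a and not b:
        raise ValueError("both interval sets are empty")
    inter = intersection_length(a, b)
    union = total_length(merge_intervals(list(a) + list(b)))
    return inter / union if union else 0.0


def _match_key(bp: Breakpoint) -> tuple:
    return (bp.chrom1, bp.chrom2, bp.strand1, bp.strand2)


def breakpoint_jaccard(
    bp_a: list[Breakpoint], bp_b: list[Breakpoint], tol_bp: int = TOL_BP_DEFAULT
) -> tuple[float, int]:
    """Jaccard index over breakpoints matched one-to-one.

    Two breakpoints match iff they share the chromosome pair and strand pair
    and both end positions differ by at most ``tol_bp``. Matching is greedy
    by total positional distance with a deterministic smaller-coordinate
    tie-break. Returns (jaccard, n_matched).
    """
    candidates = []
    for i, a in enumerate(bp_a):
        for j, b in enumerate(bp_b):
            if _match_key(a) != _match_key(b):
                continue
            d1, d2 = abs(a.pos1 - b.pos1), abs(a.pos2 - b.pos2)
            if d1 <= tol_bp and d2 <= tol_bp:
                candidates.append((d1 + d2, a.pos1, a.pos2, b.pos1, b.pos2, i, j))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for *_, i, j in sorted(candidates):
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            matched += 1
    denom = len(bp_a) + len(bp_b) - matched
    return (matched / denom if denom else 0.0), matched


def score_event_pair(
    a: AmpliconEvent,
    b: AmpliconEvent,
    tol_bp: int = TOL_BP_DEFAULT,
    theta_shared: float = THETA_SHARED,
    theta_independent: float = THETA_INDEPENDENT,
) -> SimilarityScore:
    ij = interval_jaccard(a.intervals, b.intervals)
    bj, n = breakpoint_jaccard(a.junctions, b.junctions, tol_bp)
    if bj >= theta_shared:
        verdict = "shared"
    elif ij > 0 and bj <= theta_independent:
        verdict = "independent"
    else:
        verdict = "indeterminate"
    return SimilarityScore(f"{a.sample_id}:{a.event_id}",
                           f"{b.sample_id}:{b.event_id}", ij, bj, n, verdict)


def convergence_classify(
    patient_events: dict[str, list[AmpliconEvent]],
    tol_bp: int = TOL_BP_DEFAULT,
    theta_shared: float = THETA_SHARED,
    theta_independent: float = THETA_INDEPENDENT,
) -> list[SimilarityScore]:
    """Score all cross-sample event pairs that overlap a common locus."""
    samples = sorted(patient_events)
    scores = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            for ea in patient_events[samples[i]]:
                for eb in patient_events[samples[j]]:
                    if intersection_length(ea.intervals, eb.intervals) == 0:
                        continue
                    scores.append(
                        score_event_pair(ea, eb, tol_bp, theta_shared,
                                         theta_independent)
                    )
    return scores
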