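"""Orthogonal Hi-C evidence for complex structural variants.

The framework stratifies cSVs into four structural categories and tests, per
segment (cis) or per chromosome pair (trans), whether balanced contact
frequencies around the event carry the contact signature expected of the
event class:

* cis (categories 1-2): contacts between the amplified event and its
  unamplified equal-length flanks ("event projection") are compared with
  contacts between the two flanks across the event ("flank projection").
  An ecDNA that detaches from its chromosome leaves a well of *low*
  projection contact after matrix balancing.
* trans (categories 3-4): contacts between event segments on different
  chromosomes ("intra-cSV") are compared with flank-flank contacts between
  the same chromosomes ("non-overlapping"); a multi-chromosome ecDNA shows
  *high* inter-chromosomal contact inside the event.

Rank-sum p-values are BH-adjusted within each event; an event is supported
when at least one decisive comparison has adjusted p < alpha (and, by
default, the expected direction).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMatrix, expected_by_distance, iterative_correction
from .genome import GenomeBins
from .intervals import GenomicInterval
from .stats import bh_adjust, kruskal_wallis, wilcoxon_rank_sum
from .variants import AmpliconEvent

__all__ = [
    "ValidationConfig",
    "ValidationRegions",
    "SegmentTestResult",
    "EventEvidence",
    "classify_event_category",
    "build_validation_regions",
    "extract_contact_sets",
    "test_cis",
    "test_trans",
    "validate_event",
    "summarize_support",
    "iterative_correction",
]


@dataclass
class ValidationConfig:
    """Knobs of the evidence framework (defaults = study settings)."""

    alpha: float = 0.05
    bin_size: int = 10_000
    min_pairs_per_set: int = 10
    distance_matching: bool = True
    require_direction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SegmentRegions:
    """Event bins and equal-length unamplified flanks for one segment."""

    segment: GenomicInterval
    event_bins: np.ndarray
    upstream_bins: np.ndarray   # lower coordinates
    downstream_bins: np.ndarray  # higher coordinates
    truncated: bool = False


@dataclass
class ValidationRegions:
    segments: list[SegmentRegions]
    chrom_event_bins: dict[str, np.ndarray]
    chrom_flank_bins: dict[str, np.ndarray]


@dataclass
class SegmentTestResult:
    """One decisive comparison: a cis segment or a trans chromosome pair."""

    label: str
    segment: GenomicInterval | None
    comparison: str
    n_event_pairs: int
    n_flank_pairs: int
    statistic: float = float("nan")
    p_value: float = float("nan")
    p_adjusted: float = float("nan")
    direction: str = "none"  # event_lower / event_higher / none
    testable: bool = True
    reason: str = ""


@dataclass
class EventEvidence:
    event_id: str
    sample_id: str
    event_class: str
    category: int
    segment_results: list[SegmentTestResult]
    comparisons: dict[str, list[SegmentTestResult]] = field(default_factory=dict)
    supported: bool | None = None
    support_reason: str = ""


def classify_event_category(event: AmpliconEvent) -> int:
    """Structural category: (1) one segment / one chromosome, (2) multiple
    segments / one chromosome, (3) two chromosomes, (4) more than two."""
    n_chroms = len(event.chromosomes)
    if n_chroms == 1:
        return 1 if len(event.segments) == 1 else 2
    return 3 if n_chroms == 2 else 4


def build_validation_regions(
    event: AmpliconEvent,
    all_sample_events: list[AmpliconEvent],
    bins: GenomeBins,
    config: ValidationConfig | None = None,
) -> ValidationRegions:
    """Map event segments onto bins and construct equal-length flanks.

    Flanks extend outward from each segment, skipping bins that are masked or
    overlap ANY amplified segment of ANY event in the sample, until they reach
    the segment's own bin count or a chromosome end (then flagged truncated).
    """
    config = config or ValidationConfig()
    amplified = np.zeros(bins.n_bins, dtype=bool)
    for ev in all_sample_events:
        for iv, _ in ev.segments:
            amplified[bins.bins_overlapping(iv)] = True
    mask = bins.mask

    seg_regions: list[SegmentRegions] = []
    for iv, _ in event.segments:
        ev_bins = bins.bins_overlapping(iv)
        ev_bins = ev_bins[~mask[ev_bins]]
        target = len(bins.bins_overlapping(iv))
        lo, hi = bins.chrom_range(iv.chrom)
        truncated = False

        def _walk(start: int, step: int) -> list[int]:
            nonlocal truncated
            out: list[int] = []
            b = start
            while len(out) < target and lo <= b < hi:
                if not amplified[b] and not mask[b]:
                    out.append(b)
                b += step
            if len(out) < target:
                truncated = True
            return out

        first = bins.bins_overlapping(iv)[0]
        last = bins.bins_overlapping(iv)[-1]
        up = np.array(_walk(first - 1, -1)[::-1], dtype=int)
        down = np.array(_walk(last + 1, +1), dtype=int)
        seg_regions.append(SegmentRegions(iv, ev_bins, up, down, truncated))

    chrom_event: dict[str, np.ndarray] = {}
    chrom_flank: dict[str, np.ndarray] = {}
    for sr in seg_regions:
        c = sr.segment.chrom
        chrom_event[c] = np.union1d(chrom_event.get(c, np.empty(0, int)), sr.event_bins)
        fl = np.concatenate([sr.upstream_bins, sr.downstream_bins])
        chrom_flank[c] = np.union1d(chrom_flank.get(c, np.empty(0, int)), fl)
    # flanks of one segment may fall inside another segment's event bins
    for c in chrom_flank:
        chrom_flank[c] = np.setdiff1d(chrom_flank[c], chrom_event[c])
    for sr in seg_regions:
        ev_all = chrom_event[sr.segment.chrom]
        sr.upstream_bins = np.setdiff1d(sr.upstream_bins, ev_all)
        sr.downstream_bins = np.setdiff1d(sr.downstream_bins, ev_all)
    return ValidationRegions(seg_regions, chrom_event, chrom_flank)


# ----------------------------------------------------------- value sets

def _within_pairs(matrix: ContactMatrix, idx: np.ndarray):
    """Values and separations over distinct unordered bin pairs inside idx."""
    if len(idx) < 2:
        return np.empty(0), np.empty(0, int)
    sub = matrix.submatrix(idx, idx)
    iu = np.triu_indices(len(idx), k=1)
    seps = np.abs(idx[iu[0]] - idx[iu[1]])
    return sub[iu], seps


def _between_pairs(matrix: ContactMatrix, a: np.ndarray, b: np.ndarray):
    if len(a) == 0 or len(b) == 0:
        return np.empty(0), np.empty(0, int)
    sub = matrix.submatrix(a, b)
    seps = np.abs(a[:, None] - b[None, :])
    return sub.ravel(), seps.ravel()


def _decay_normalize(values, seps, expected):
    e = expected[seps]
    ok = np.isfinite(e) & (e > 0)
    return values[ok] / e[ok], seps[ok]


def extract_contact_sets(
    matrix: ContactMatrix,
    regions: ValidationRegions,
    segment: SegmentRegions,
    config: ValidationConfig | None = None,
    expected: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """The four labeled cis value sets for one segment.

    WITHIN_EVENT: unordered pairs inside the segment; WITHIN_FLANK: pairs
    inside each flank (same flank only); EVENT_PROJECTION: (event, flank)
    pairs; FLANK_PROJECTION: (upstream, downstream) pairs. With
    ``distance_matching`` on, both projection sets are decay-normalized
    (observed / chromosome-wide expected at that separation) and restricted
    to the intersection of their separation ranges.
    """
    config = config or ValidationConfig()
    we, _ = _within_pairs(matrix, segment.event_bins)
    wu, _ = _within_pairs(matrix, segment.upstream_bins)
    wd, _ = _within_pairs(matrix, segment.downstream_bins)
    flank = np.concatenate([segment.upstream_bins, segment.downstream_bins])
    ep, ep_s = _between_pairs(matrix, segment.event_bins, flank)
    fp, fp_s = _between_pairs(matrix, segment.upstream_bins, segment.downstream_bins)
    if config.distance_matching and len(ep) and len(fp):
        if expected is None:
            expected = expected_by_distance(matrix, segment.segment.chrom)
        ep, ep_s = _decay_normalize(ep, ep_s, expected)
        fp, fp_s = _decay_normalize(fp, fp_s, expected)
        if len(ep_s) and len(fp_s):
            lo = max(ep_s.min(), fp_s.min())
            hi = min(ep_s.max(), fp_s.max())
            ep = ep[(ep_s >= lo) & (ep_s <= hi)]
            fp = fp[(fp_s >= lo) & (fp_s <= hi)]
    return {
        "WITHIN_EVENT": we,
        "WITHIN_FLANK": np.concatenate([wu, wd]),
        "EVENT_PROJECTION": ep,
        "FLANK_PROJECTION": fp,
    }


def _direction(event_vals: np.ndarray, flank_vals: np.ndarray) -> str:
    me, mf = np.median(event_vals), np.median(flank_vals)
    if me < mf:
        return "event_lower"
    if me > mf:
        return "event_higher"
    return "none"


def _compare(label, segment, comparison, ev, fl, min_pairs) -> SegmentTestResult:
    r = SegmentTestResult(label, segment, comparison, len(ev), len(fl))
    if len(ev) < min_pairs or len(fl) < min_pairs:
        r.testable = False
        r.reason = (
            f"too few pairs (event={len(ev)}, flank={len(fl)}, "
            f"need {min_pairs})"
        )
        return r
    t = wilcoxon_rank_sum(ev, fl, "two_sided")
    r.statistic, r.p_value = t.statistic, t.p_value
    r.direction = _direction(ev, fl)
    return r


def _finalize(evidence: EventEvidence, decisive, expected_direction, config):
    testable = [r for r in decisive if r.testable]
    if not testable:
        evidence.supported = None
        evidence.support_reason = "no testable comparison"
        return evidence
    adj = bh_adjust([r.p_value for r in testable])
    for r, a in zip(testable, adj):
        r.p_adjusted = float(max(a, r.p_value))
    hits = [
        r for r in testable
        if r.p_adjusted < config.alpha
        and (not config.require_direction or r.direction == expected_direction)
    ]
    evidence.supported = bool(hits)
    evidence.support_reason = (
        f"{len(hits)} of {len(testable)} comparisons significant "
        f"(adjusted p < {config.alpha})"
        + (f", direction {expected_direction}" if config.require_direction else "")
    )
    return evidence


def test_cis(
    event: AmpliconEvent,
    matrix: ContactMatrix,
    regions: ValidationRegions,
    config: ValidationConfig | None = None,
) -> EventEvidence:
    """Category 1-2 evidence: per-segment event vs flank projection."""
    config = config or ValidationConfig()
    category = classify_event_category(event)
    if category not in (1, 2):
        raise ValueError(f"test_cis requires category 1 or 2, got {category}")
    if not matrix.balanced:
        raise ValueError("matrix must be balanced (run iterative_correction)")
    exp_cache: dict[str, np.ndarray] = {}
    decisive, within = [], []
    for sr in regions.segments:
        chrom = sr.segment.chrom
        if chrom not in exp_cache:
            exp_cache[chrom] = expected_by_distance(matrix, chrom)
        sets = extract_contact_sets(matrix, regions, sr, config, exp_cache[chrom])
        label = f"{chrom}:{sr.segment.start}-{sr.segment.end}"
        decisive.append(
            _compare(label, sr.segment, "projection",
                     sets["EVENT_PROJECTION"], sets["FLANK_PROJECTION"],
                     config.min_pairs_per_set)
        )
        within.append(
            _compare(label, sr.segment, "within_vs_flank",
                     sets["WITHIN_EVENT"], sets["WITHIN_FLANK"],
                     config.min_pairs_per_set)
        )
    w_testable = [r for r in within if r.testable]
    if w_testable:
        for r, a in zip(w_testable, bh_adjust([r.p_value for r in w_testable])):
            r.p_adjusted = float(max(a, r.p_value))
    ev = EventEvidence(
        event.event_id, event.sample_id, event.event_class, category,
        segment_results=decisive,
        comparisons={"projection": decisive, "within_vs_flank": within},
    )
    return _finalize(ev, decisive, "event_lower", config)


def test_trans(
    event: AmpliconEvent,
    matrix: ContactMatrix,
    regions: ValidationRegions,
    config: ValidationConfig | None = None,
) -> EventEvidence:
    """Category 3-4 evidence: intra-cSV vs non-overlapping flank contacts,
    per chromosome pair."""
    config = config or ValidationConfig()
    category = classify_event_category(event)
    if category not in (3, 4):
        raise ValueError(f"test_trans requires category 3 or 4, got {category}")
    if not matrix.balanced:
        raise ValueError("matrix must be balanced (run iterative_correction)")
    chroms = [c for c in event.chromosomes if c in regions.chrom_event_bins]
    decisive, overlapping = [], []
    for i in range(len(chroms)):
        for j in range(i + 1, len(chroms)):
            ca, cb = chroms[i], chroms[j]
            label = f"{ca}|{cb}"
            lo_a, hi_a = matrix.bins.chrom_range(ca)
            lo_b, hi_b = matrix.bins.chrom_range(cb)
            if matrix.values[lo_a:hi_a, lo_b:hi_b].nnz == 0:
                r = SegmentTestResult(label, None, "intra_csv_vs_non_overlapping",
                                      0, 0, testable=False,
                                      reason="no trans pixels stored")
                decisive.append(r)
                continue
            ea, eb = regions.chrom_event_bins[ca], regions.chrom_event_bins[cb]
            fa = regions.chrom_flank_bins.get(ca, np.empty(0, int))
            fb = regions.chrom_flank_bins.get(cb, np.empty(0, int))
            intra, _ = _between_pairs(matrix, ea, eb)
            non, _ = _between_pairs(matrix, fa, fb)
            ov = np.concatenate(
                [_between_pairs(matrix, ea, fb)[0],
                 _between_pairs(matrix, eb, fa)[0]]
            )
            decisive.append(
                _compare(label, None, "intra_csv_vs_non_overlapping",
                         intra, non, config.min_pairs_per_set)
            )
            overlapping.append(
                _compare(label, None, "csv_overlapping_vs_non_overlapping",
                         ov, non, config.min_pairs_per_set)
            )
    o_testable = [r for r in overlapping if r.testable]
    if o_testable:
        for r, a in zip(o_testable, bh_adjust([r.p_value for r in o_testable])):
            r.p_adjusted = float(max(a, r.p_value))
    ev = EventEvidence(
        event.event_id, event.sample_id, event.event_class, category,
        segment_results=decisive,
        comparisons={
            "intra_csv_vs_non_overlapping": decisive,
            "csv_overlapping_vs_non_overlapping": overlapping,
        },
    )
    return _finalize(ev, decisive, "event_higher", config)


def validate_event(
    event: AmpliconEvent,
    matrix: ContactMatrix,
    all_sample_events: list[AmpliconEvent],
    config: ValidationConfig | None = None,
) -> EventEvidence:
    """Dispatch an event to the cis or trans framework by category."""
    config = config or ValidationConfig()
    regions = build_validation_regions(event, all_sample_events, matrix.bins, config)
    if classify_event_category(event) in (1, 2):
        return test_cis(event, matrix, regions, config)
    return test_trans(event, matrix, regions, config)


def summarize_support(
    evidences: list[EventEvidence],
    purities: dict[str, float] | None = None,
    event_weighted_cn: dict[str, float] | None = None,
) -> dict:
    """Cohort-level support fractions and purity / event-CN associations."""
    if not evidences:
        raise ValueError("need at least one evidence")
    testable = [e for e in evidences if e.supported is not None]
    n_sup = sum(e.supported for e in testable)
    by_class: dict[str, tuple[int, int]] = {}
    for e in testable:
        s, t = by_class.get(e.event_class, (0, 0))
        by_class[e.event_class] = (s + int(e.supported), t + 1)
    out = {
        "n_events": len(evidences),
        "n_testable": len(testable),
        "n_supported": int(n_sup),
        "fraction_supported": n_sup / len(testable) if testable else float("nan"),
        "fraction_by_class": {
            c: s / t for c, (s, t) in sorted(by_class.items())
        },
    }

    def _kw(value_of):
        groups = [[], []]
        for e in testable:
            v = value_of(e)
            if v is not None:
                groups[int(e.supported)].append(v)
        if not groups[0] or not groups[1]:
            return None  # single group: association not computable
        return kruskal_wallis(groups)

    if purities is not None:
        out["purity_test"] = _kw(lambda e: purities.get(e.sample_id))
    if event_weighted_cn is not None:
        out["event_cn_test"] = _kw(lambda e: event_weighted_cn.get(e.event_id))
    return out
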