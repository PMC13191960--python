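import numpy as np
import pytest

from hicsv.chromothripsis import (
    ChromothripsisConfig,
    call_chromothripsis,
    count_window_features,
    csv_chromothripsis_association,
)
from hicsv.intervals import GenomicInterval as GI
from hicsv.simulate import simulate_chromothripsis
from hicsv.variants import (
    AmpliconEvent,
    Breakpoint,
    CopyNumberSegment,
    CopyNumberSegmentSet,
)

CHROM_LEN = 12_000_000
REGION = (4_000_000, 6_400_000)  # fits inside one 2.5 Mb window


def _counts(n_inv, n_del, n_switch, seed=0):
    bps, segs = simulate_chromothripsis(
        "chr5", CHROM_LEN, REGION, n_inv, n_del, n_switch, seed=seed
    )
    return count_window_features(bps, segs, "chr5", CHROM_LEN)


class TestThresholds:
    def test_exact_threshold_calls_positive(self):
        verdict, regions = call_chromothripsis({"chr5": _counts(15, 10, 15)})
        assert verdict["chr5"]
        assert regions

    @pytest.mark.parametrize(
        "n_inv, n_del, n_switch", [(14, 10, 15), (15, 9, 15), (15, 10, 14)]
    )
    def test_any_decrement_calls_negative(self, n_inv, n_del, n_switch):
        verdict, _ = call_chromothripsis(
            {"chr5": _counts(n_inv, n_del, n_switch)}
        )
        assert not verdict["chr5"]

    def test_no_svs_all_windows_negative(self):
        segs = CopyNumberSegmentSet(
            "s", [CopyNumberSegment(GI("chr5", 0, CHROM_LEN), 2.0)]
        )
        wc = count_window_features([], segs, "chr5", CHROM_LEN)
        assert not any(w.called for w in wc)


class TestWindowCounting:
    def test_both_breakends_must_be_inside(self):
        cfg = ChromothripsisConfig()
        bps = [Breakpoint.make("chr5", 100_000, "+", "chr5", 3_000_000, "+")]
        segs = CopyNumberSegmentSet(
            "s", [CopyNumberSegment(GI("chr5", 0, CHROM_LEN), 2.0)]
        )
        wc = count_window_features(bps, segs, "chr5", CHROM_LEN, cfg)
        assert all(w.n_inversions == 0 for w in wc)

    def test_cn_switch_needs_magnitude_above_epsilon(self):
        segs = CopyNumberSegmentSet(
            "s",
            [CopyNumberSegment(GI("chr5", 0, 1_000_000), 2.0),
             CopyNumberSegment(GI("chr5", 1_000_000, 2_000_000), 2.4),
             CopyNumberSegment(GI("chr5", 2_000_000, CHROM_LEN), 3.5)],
        )
        wc = count_window_features([], segs, "chr5", CHROM_LEN)
        # only the 2.4 -> 3.5 boundary exceeds |dCN| > 0.5
        assert max(w.n_cn_switches for w in wc) == 1

    def test_translation_invariance_by_step_multiples(self):
        cfg = ChromothripsisConfig()
        shift = 7 * cfg.step
        bps, segs = simulate_chromothripsis(
            "chr5", CHROM_LEN, REGION, 5, 5, 5, seed=3
        )
        bps_shifted = [
            Breakpoint.make(b.chrom1, b.pos1 + shift, b.strand1,
                            b.chrom2, b.pos2 + shift, b.strand2, b.sv_type)
            for b in bps
        ]
        segs_shifted = CopyNumberSegmentSet(
            "s",
            [CopyNumberSegment(
                GI("chr5", s.interval.start + shift,
                   min(s.interval.end + shift, CHROM_LEN + shift)),
                s.copy_number)
             for s in segs],
        )
        a = count_window_features(bps, segs, "chr5", CHROM_LEN, cfg)
        b = count_window_features(bps_shifted, segs_shifted, "chr5",
                                  CHROM_LEN + shift, cfg)
        k = shift // cfg.step
        for wa, wb in zip(a[: len(a) - k], b[k:]):
            assert (wa.n_inversions, wa.n_deletions, wa.n_cn_switches) == (
                wb.n_inversions, wb.n_deletions, wb.n_cn_switches
            )

    def test_adding_inversion_never_decreases_counts(self):
        bps, segs = simulate_chromothripsis(
            "chr5", CHROM_LEN, REGION, 5, 5, 5, seed=4
        )
        base = count_window_features(bps, segs, "chr5", CHROM_LEN)
        extra = bps + [
            Breakpoint.make("chr5", 5_000_500, "+", "chr5", 5_100_500, "+")
        ]
        more = count_window_features(extra, segs, "chr5", CHROM_LEN)
        assert all(
            m.n_inversions >= b.n_inversions for b, m in zip(base, more)
        )

    def test_called_flag_recomputable(self):
        cfg = ChromothripsisConfig()
        for w in _counts(15, 10, 15):
            assert w.called == (
                w.n_inversions >= cfg.min_inversions
                and w.n_cn_switches >= cfg.min_cn_switches
                and w.n_deletions >= cfg.min_deletions
            )

    def test_overlapping_called_windows_merge(self):
        wc = _counts(20, 12, 20)
        n_called = sum(w.called for w in wc)
        _, regions = call_chromothripsis({"chr5": wc})
        assert n_called > 1 and len(regions) == 1


class TestAssociation:
    def test_perfect_association_extreme_p(self):
        events = {}
        calls = {}
        for i in range(20):
            sid = f"s{i}"
            has = i < 10
            calls[(sid, "chr8")] = has
            events[sid] = (
                [AmpliconEvent("e", sid, "ecDNA", [(GI("chr8", 0, 100), 9.0)])]
                if has else []
            )
        res = csv_chromothripsis_association(events, calls)
        # hypergeometric extreme for a 10/10 diagonal table
        assert res.p_value < 1e-4

    def test_single_pair_degenerate_margin(self):
        events = {"s": [AmpliconEvent("e", "s", "BFB", [(GI("chr1", 0, 9), 5)])]}
        calls = {("s", "chr1"): True}
        assert csv_chromothripsis_association(events, calls).p_value == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            csv_chromothripsis_association({}, {})

    def test_independent_simulation_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(120):
            calls, events = {}, {}
            for i in range(40):
                sid = f"s{i}"
                calls[(sid, "chr8")] = bool(rng.random() < 0.4)
                events[sid] = (
                    [AmpliconEvent("e", sid, "ecDNA",
                                   [(GI("chr8", 0, 100), 9.0)])]
                    if rng.random() < 0.4 else []
                )
            ps.append(csv_chromothripsis_association(events, calls).p_value)
        # null p-values should not pile up near 0
        assert np.mean(np.asarray(ps) < 0.05) < 0.12
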