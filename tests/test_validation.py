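import numpy as np
import pytest
import scipy.sparse as sp

from hicsv.contacts import ContactMatrix
from hicsv.genome import GenomeBins
from hicsv.intervals import GenomicInterval as GI
from hicsv.simulate import cis_scenario, simulate_hic, trans_scenario
from hicsv.validation import (
    ValidationConfig,
    build_validation_regions,
    classify_event_category,
    extract_contact_sets,
    iterative_correction,
    summarize_support,
)
from hicsv.validation import test_cis as run_cis_test
from hicsv.validation import test_trans as run_trans_test
from hicsv.variants import AmpliconEvent


def _event(segs, cls="ecDNA", sample="s1"):
    return AmpliconEvent("e1", sample, cls, [(iv, 20.0) for iv in segs])


class TestCategory:
    @pytest.mark.parametrize(
        "segs, expected",
        [
            ([GI("chrX", 0, 100)], 1),
            ([GI("chr8", 0, 100), GI("chr8", 500, 600), GI("chr8", 900, 950)], 2),
            ([GI("chr18", 0, 100), GI("chrX", 0, 100)], 3),
            ([GI("chr1", 0, 100), GI("chr2", 0, 100), GI("chr3", 0, 100)], 4),
        ],
    )
    def test_quoted_definition(self, segs, expected):
        assert classify_event_category(_event(segs)) == expected


class TestRegions:
    def test_mid_chromosome_flanks_contiguous(self, small_bins, mid_event):
        reg = build_validation_regions(mid_event, [mid_event], small_bins)
        sr = reg.segments[0]
        assert len(sr.event_bins) == 10
        assert list(sr.upstream_bins) == list(range(5, 15))
        assert list(sr.downstream_bins) == list(range(25, 35))
        assert not sr.truncated

    def test_flank_truncated_at_chromosome_start(self, small_bins):
        # 10-bin segment sitting 5 bins from the chromosome start: only
        # 5 upstream bins exist, so the flank is truncated and flagged
        ev = _event([GI("chr1", 50_000, 150_000)])
        reg = build_validation_regions(ev, [ev], small_bins)
        sr = reg.segments[0]
        assert len(sr.upstream_bins) == 5
        assert sr.truncated

    def test_flank_skips_neighboring_event(self, small_bins, mid_event):
        other = AmpliconEvent(
            "e2", "s1", "BFB", [(GI("chr1", 100_000, 130_000), 9.0)]
        )
        reg = build_validation_regions(mid_event, [mid_event, other], small_bins)
        sr = reg.segments[0]
        all_event_bins = set(range(15, 25)) | set(range(10, 13))
        assert not set(sr.upstream_bins) & all_event_bins
        assert not set(sr.downstream_bins) & all_event_bins
        assert len(sr.upstream_bins) == 10  # extended outward past the other

    def test_flanks_never_intersect_any_event(self, rng, small_bins):
        for _ in range(20):
            s = int(rng.integers(0, 30))
            ev = _event([GI("chr1", s * 10_000, (s + int(rng.integers(1, 8)))
                            * 10_000)])
            reg = build_validation_regions(ev, [ev], small_bins)
            sr = reg.segments[0]
            overlap = set(sr.upstream_bins) | set(sr.downstream_bins)
            assert not overlap & set(sr.event_bins)


def _uniform_matrix(bins, value=3.0):
    n = bins.n_bins
    return ContactMatrix(bins, sp.csr_matrix(np.full((n, n), value)),
                         balanced=True, mask_zero_coverage=False)


class TestContactSets:
    def test_projection_combinatorics(self):
        bins = GenomeBins({"chr1": 200_000}, bin_size=10_000)
        ev = _event([GI("chr1", 80_000, 110_000)])  # 3 bins
        reg = build_validation_regions(ev, [ev], bins)
        m = _uniform_matrix(bins)
        cfg = ValidationConfig(distance_matching=False)
        sets = extract_contact_sets(m, reg, reg.segments[0], cfg)
        assert len(sets["EVENT_PROJECTION"]) == 3 * 6
        assert len(sets["FLANK_PROJECTION"]) == 9
        assert len(sets["WITHIN_EVENT"]) == 3
        for v in sets.values():
            assert np.allclose(v, 3.0)

    def test_masked_bin_pairs_absent(self):
        bins = GenomeBins({"chr1": 200_000}, bin_size=10_000)
        bins.mask[6] = True  # inside the upstream flank
        ev = _event([GI("chr1", 90_000, 120_000)])
        reg = build_validation_regions(ev, [ev], bins)
        assert 6 not in reg.segments[0].upstream_bins


class TestCisTrans:
    def test_simulated_ecdna_supported_event_lower(self, rng):
        scen, ev = cis_scenario(rng, amplification=10, purity=0.7)
        m = iterative_correction(simulate_hic(scen, seed=7))
        cfg = ValidationConfig()
        reg = build_validation_regions(ev, [ev], m.bins, cfg)
        evd = run_cis_test(ev, m, reg, cfg)
        assert evd.supported is True
        assert evd.segment_results[0].direction == "event_lower"

    def test_simulated_trans_ecdna_supported(self, rng):
        scen, ev = trans_scenario(rng, amplification=10, purity=0.7)
        m = iterative_correction(simulate_hic(scen, seed=9))
        cfg = ValidationConfig()
        reg = build_validation_regions(ev, [ev], m.bins, cfg)
        evd = run_trans_test(ev, m, reg, cfg)
        assert evd.supported is True
        assert evd.segment_results[0].direction == "event_higher"

    def test_wrong_category_rejected(self, rng):
        scen, ev = cis_scenario(rng)
        m = iterative_correction(simulate_hic(scen, seed=1))
        reg = build_validation_regions(ev, [ev], m.bins)
        with pytest.raises(ValueError, match="category"):
            run_trans_test(ev, m, reg)

    def test_untestable_event_supported_is_absent(self):
        # event covering the whole chromosome leaves no flank space
        bins = GenomeBins({"chr1": 300_000}, bin_size=10_000)
        ev = _event([GI("chr1", 0, 300_000)])
        m = _uniform_matrix(bins)
        reg = build_validation_regions(ev, [ev], bins)
        evd = run_cis_test(ev, m, reg)
        assert evd.supported is None
        assert "no testable" in evd.support_reason

    def test_supported_flag_recomputable_from_results(self, rng):
        scen, ev = cis_scenario(rng, amplification=10)
        m = iterative_correction(simulate_hic(scen, seed=5))
        cfg = ValidationConfig()
        reg = build_validation_regions(ev, [ev], m.bins, cfg)
        evd = run_cis_test(ev, m, reg, cfg)
        recomputed = any(
            r.testable and r.p_adjusted < cfg.alpha and r.direction == "event_lower"
            for r in evd.segment_results
        )
        assert recomputed == evd.supported

    def test_missing_trans_pixels_untestable(self):
        bins = GenomeBins({"chrA": 200_000, "chrB": 200_000}, bin_size=10_000)
        n = bins.n_bins
        dense = np.zeros((n, n))
        for lo, hi in (bins.chrom_range("chrA"), bins.chrom_range("chrB")):
            dense[lo:hi, lo:hi] = 2.0  # cis only, no trans pixels
        m = ContactMatrix(bins, sp.csr_matrix(dense), balanced=True,
                          mask_zero_coverage=False)
        ev = _event([GI("chrA", 50_000, 100_000), GI("chrB", 50_000, 100_000)])
        reg = build_validation_regions(ev, [ev], bins)
        evd = run_trans_test(ev, m, reg)
        assert evd.supported is None
        assert "no trans pixels" in evd.segment_results[0].reason


class TestSummary:
    def _evidence(self, event_id, sample, cls, supported):
        from hicsv.validation import EventEvidence

        return EventEvidence(event_id, sample, cls, 1, [], supported=supported)

    def test_fraction_supported(self):
        evs = [self._evidence(f"e{i}", f"s{i}", "ecDNA", i < 3) for i in range(4)]
        out = summarize_support(evs)
        assert out["fraction_supported"] == 0.75

    def test_untestable_excluded(self):
        evs = [self._evidence("e0", "s0", "ecDNA", True),
               self._evidence("e1", "s1", "BFB", None)]
        out = summarize_support(evs)
        assert out["n_testable"] == 1

    def test_single_group_association_not_computable(self):
        evs = [self._evidence(f"e{i}", f"s{i}", "ecDNA", True) for i in range(3)]
        out = summarize_support(evs, purities={f"s{i}": 0.5 for i in range(3)})
        assert out["purity_test"] is None

    def test_purity_association_detected(self, rng):
        # support probability increases with purity -> KW should fire
        evs, purities = [], {}
        for i in range(200):
            pur = float(rng.uniform(0.2, 0.95))
            supported = bool(rng.random() < pur)
            evs.append(self._evidence(f"e{i}", f"s{i}", "ecDNA", supported))
            purities[f"s{i}"] = pur
        out = summarize_support(evs, purities=purities)
        assert out["purity_test"].p_value < 0.05
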