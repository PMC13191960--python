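"""Statistical primitives versus independent oracles (enumeration, scipy,
statsmodels, explicit normal equations)."""
import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hicsv.stats import (
    bh_adjust,
    fisher_exact_2x2,
    kruskal_wallis,
    nested_f_test,
    wilcoxon_rank_sum,
)


def _exact_wilcoxon_oracle(x, y, alternative):
    """Brute-force: enumerate all rank assignments of the pooled sample."""
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + \
        0.5 * sum(1 for xi in x for yi in y if xi == yi)
    mid = n1 * n2 / 2
    hits = total = 0
    for combo in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        if alternative == "less":
            hits += u <= u_obs
        elif alternative == "greater":
            hits += u >= u_obs
        else:
            hits += abs(u - mid) >= abs(u_obs - mid) - 1e-12
    return hits / total


class TestWilcoxon:
    def test_frozen_examples(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)
        assert wilcoxon_rank_sum([5], [5]).p_value == 1.0
        assert wilcoxon_rank_sum([1, 2], [3, 4], "less").p_value == pytest.approx(1 / 6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(derandomize=True, max_examples=80)
    @given(
        st.lists(st.integers(0, 10_000), min_size=1, max_size=5),
        st.lists(st.integers(0, 10_000), min_size=1, max_size=5),
        st.sampled_from(["two_sided", "less", "greater"]),
    )
    def test_exact_path_matches_enumeration_oracle(self, xr, yr, alternative):
        # map to distinct values so there are no ties
        pooled = sorted(set(xr + [v + 20_000 for v in yr]))
        if len(pooled) < len(xr) + len(yr):
            return
        x, y = xr, [v + 20_000 for v in yr]
        got = wilcoxon_rank_sum(x, y, alternative)
        assert got.method == "wilcoxon_exact"
        assert got.p_value == pytest.approx(
            _exact_wilcoxon_oracle(x, y, alternative)
        )

    def test_normal_path_tracks_scipy(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 35)
        got = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert got.statistic == pytest.approx(ref.statistic)
        assert got.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_rejection_rate_calibrated(self, rng):
        # both samples from one continuous distribution; alpha=0.05 two-sided
        n_rep, alpha = 2_000, 0.05
        rejections = sum(
            wilcoxon_rank_sum(rng.normal(size=12), rng.normal(size=12)).p_value
            < alpha
            for _ in range(n_rep)
        )
        ci_half = 2.576 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) < ci_half


class TestBH:
    def test_frozen_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([0.04, 0.01]) == pytest.approx([0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_properties_and_statsmodels_agreement(self, p):
        from statsmodels.stats.multitest import multipletests

        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref)


class TestFisher:
    def test_frozen_examples(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]).p_value == pytest.approx(
            0.4857142857, rel=1e-6
        )
        assert fisher_exact_2x2([[0, 5], [5, 0]]).p_value == pytest.approx(
            2 / 252, rel=1e-9
        )
        assert fisher_exact_2x2([[0, 0], [3, 4]]).p_value == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_hypergeometric_masses_sum_to_one(self):
        a, b, c, d = 4, 6, 7, 13
        n, r1, c1 = a + b + c + d, a + b, a + c
        rv = sps.hypergeom(n, r1, c1)
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        assert rv.pmf(np.arange(lo, hi + 1)).sum() == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_scipy_on_small_tables(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        assert fisher_exact_2x2(t).p_value == pytest.approx(
            sps.fisher_exact(t)[1], rel=1e-8, abs=1e-12
        )


class TestKruskalWallis:
    def test_frozen_h_statistic(self):
        assert kruskal_wallis([[1, 2, 3], [4, 5, 6]]).statistic == pytest.approx(
            3.857, abs=5e-4
        )

    def test_degenerate_groups(self):
        assert kruskal_wallis([[1, 2], [1, 2]]).statistic == pytest.approx(0.0)
        assert kruskal_wallis([[2, 2], [2, 2], [2]]).statistic == 0.0

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        got = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert got.statistic == pytest.approx(ref.statistic)
        assert got.p_value == pytest.approx(ref.pvalue)


class TestNestedF:
    def test_perfect_reduced_fit_gives_zero_f(self):
        cn = np.array([1.0, 2, 3, 4, 5, 6])
        y = 2 + 0.5 * cn
        ec = np.array([0, 1, 0, 1, 0, 1])
        f, p = nested_f_test(y, cn, ec)
        assert f == 0.0 and p == 1.0

    def test_perfect_full_fit_gives_infinity_sentinel(self):
        cn = np.array([1.0, 2, 3, 4, 5, 6])
        ec = np.array([0, 1, 0, 1, 0, 1])
        y = cn + 2 * ec
        f, p = nested_f_test(y, cn, ec)
        assert math.isinf(f) and p == 0.0

    def test_collinear_design_rejected(self):
        cn = np.array([1.0, 2, 3, 4])
        with pytest.raises(ValueError, match="collinear"):
            nested_f_test([1.0, 2, 3, 4], cn, cn)

    def test_matches_normal_equations_oracle_n8(self):
        # fixed printed inputs; oracle = explicit matrix solve
        y = np.array([2.1, 3.9, 4.2, 6.1, 5.8, 8.2, 7.9, 10.1])
        cn = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0, 5.0])
        ec = np.array([0, 0, 1, 0, 1, 0, 1, 1])

        def sse(cols):
            x = np.column_stack(cols)
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            r = y - x @ beta
            return r @ r

        one = np.ones(8)
        sse_r = sse([one, cn])
        sse_f = sse([one, cn, ec])
        f_oracle = (sse_r - sse_f) / (sse_f / 5)
        f, p = nested_f_test(y, cn, ec)
        assert f == pytest.approx(f_oracle, abs=1e-8)
        assert p == pytest.approx(float(sps.f.sf(f_oracle, 1, 5)))
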