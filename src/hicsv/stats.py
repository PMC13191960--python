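"""Statistical primitives used by every analysis stage.

The test statistics are computed here from first principles (exact
enumeration for small rank-sum problems, hypergeometric enumeration for the
2x2 exact test, tie-corrected H, nested OLS F). Reference distributions
(normal, chi-squared, F, hypergeometric pmf) come from scipy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _sps

ALTERNATIVES = ("two_sided", "less", "greater")

#: combined sample size at or below which the rank-sum test enumerates
#: the exact null distribution (no-ties inputs only)
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str = "two_sided"
    method: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the Mann-Whitney U of ``x``. With combined n <= 12 and no
    ties the p-value is exact by enumeration of all rank assignments;
    otherwise a normal approximation with tie and continuity correction is
    used. ``alternative='less'`` tests whether ``x`` tends to be smaller.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = len(np.unique(pooled)) < n1 + n2

    if n1 + n2 <= EXACT_WILCOXON_MAX_N and not has_ties:
        # enumerate U over all C(n1+n2, n1) assignments of ranks to x
        mid = n1 * n2 / 2
        all_ranks = range(1, n1 + n2 + 1)
        count = total = 0
        for combo in combinations(all_ranks, n1):
            uu = sum(combo) - n1 * (n1 + 1) / 2
            total += 1
            if alternative == "less":
                hit = uu <= u
            elif alternative == "greater":
                hit = uu >= u
            else:
                hit = abs(uu - mid) >= abs(u - mid) - 1e-12
            count += hit
        return TestResult(u, count / total, alternative, "wilcoxon_exact")

    mean = n1 * n2 / 2
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, alternative, "wilcoxon_normal")
    sd = math.sqrt(var)
    if alternative == "less":
        p = _sps.norm.cdf((u - mean + 0.5) / sd)
    elif alternative == "greater":
        p = _sps.norm.sf((u - mean - 0.5) / sd)
    else:
        z = max(0.0, (abs(u - mean) - 0.5)) / sd
        p = 2 * _sps.norm.sf(z)
    return TestResult(u, min(1.0, float(p)), alternative, "wilcoxon_normal")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table of counts.

    p = sum of hypergeometric probabilities (margins fixed) of all tables at
    most as probable as the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("cells must be non-negative integers")
        t = np.round(t).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        odds = math.nan
        return TestResult(odds, 1.0, "two_sided", "fisher_exact")
    rv = _sps.hypergeom(n, r1, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(lo, hi + 1)
    pmfs = rv.pmf(ks)
    p = float(pmfs[pmfs <= p_obs * (1 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return TestResult(odds, min(1.0, p), "two_sided", "fisher_exact")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi2(k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1 - (t**3 - t).sum() / (n**3 - n) if n > 1 else 1.0
    if correction == 0:
        return TestResult(0.0, 1.0, "two_sided", "kruskal_wallis")
    h /= correction
    p = float(_sps.chi2.sf(h, len(groups) - 1))
    return TestResult(float(h), p, "two_sided", "kruskal_wallis")


def nested_f_test(y, covariate_cn, indicator_ecdna, _tol: float = 1e-10):
    """Extra-sum-of-squares F test: does an ecDNA indicator improve an
    intercept+CN linear model of expression?

    Returns ``(F, p)``. A perfect full-model fit with remaining reduced-model
    error is reported as ``(inf, 0.0)``; when both models fit perfectly the
    indicator adds nothing and ``(0.0, 1.0)`` is returned.
    """
    y = np.asarray(y, dtype=float)
    cn = np.asarray(covariate_cn, dtype=float)
    ec = np.asarray(indicator_ecdna, dtype=float)
    n = y.size
    if not (cn.size == n == ec.size):
        raise ValueError("inputs must have equal length")
    if n < 4:
        raise ValueError("need n >= 4")
    x_full = np.column_stack([np.ones(n), cn, ec])
    if np.linalg.matrix_rank(x_full) < 3:
        raise ValueError(
            "full design matrix is rank-deficient: the ecDNA indicator is "
            "collinear with the intercept/CN covariate"
        )
    x_red = x_full[:, :2]

    def sse(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    sse_r, sse_f = sse(x_red), sse(x_full)
    scale = max(1.0, float(y @ y))
    if sse_f <= _tol * scale:
        if sse_r - sse_f <= _tol * scale:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (sse_r - sse_f) / (sse_f / (n - 3))
    f = max(0.0, f)
    p = float(_sps.f.sf(f, 1, n - 3))
    return f, p
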