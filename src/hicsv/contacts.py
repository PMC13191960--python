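"""Symmetric binned Hi-C contact matrices and iterative-correction balancing."""
from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .genome import GenomeBins


class ContactMatrix:
    """Symmetric sparse contact matrix over a :class:`GenomeBins` binning.

    Entries touching masked bins are absent. ``balanced`` marks matrices that
    went through iterative correction; the per-bin ``bias`` vector then
    satisfies ``balanced = raw / (bias_i * bias_j)``.
    """

    def __init__(
        self,
        bins: GenomeBins,
        values: sp.spmatrix,
        balanced: bool = False,
        bias: np.ndarray | None = None,
        mask_zero_coverage: bool = True,
    ):
        values = sp.csr_matrix(values, dtype=float)
        if values.shape != (bins.n_bins, bins.n_bins):
            raise ValueError("matrix shape does not match binning")
        if values.nnz and values.data.min() < 0:
            raise ValueError("negative contact value")
        asym = abs(values - values.T)
        if asym.nnz and asym.max() > 1e-9 * max(1.0, values.max()):
            raise ValueError("contact matrix is not symmetric")
        self.bins = bins
        self.balanced = bool(balanced)
        self.bias = None if bias is None else np.asarray(bias, dtype=float)
        if mask_zero_coverage:
            marg = np.asarray(values.sum(axis=1)).ravel()
            bins.mask |= marg == 0
        # zero out masked rows/columns so they are truly absent
        if bins.mask.any():
            keep = sp.diags((~bins.mask).astype(float))
            values = keep @ values @ keep
            values.eliminate_zeros()
        self.values = sp.csr_matrix(values)

    def value(self, i: int, j: int) -> float:
        return float(self.values[i, j])

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def submatrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(np.asarray(rows), np.asarray(cols))].toarray()

    def pair_values(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Values for the cartesian product rows x cols (zeros included)."""
        return self.submatrix(rows, cols).ravel()


def iterative_correction(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-6
) -> ContactMatrix:
    """Balance a raw contact matrix with the iterative correction (ICE) method.

    Alternately rescales rows/columns until every unmasked marginal equals the
    mean marginal within ``tol`` (relative). Masked bins are excluded from the
    criterion and stay absent. Idempotent on balanced input up to ``tol``.
    """
    mask = matrix.bins.mask
    dense = matrix.dense()
    bias = np.ones(matrix.bins.n_bins)
    unm = ~mask
    converged = False
    for _ in range(max_iter):
        marg = dense.sum(axis=1)
        m = marg[unm]
        mean = m.mean() if m.size else 0.0
        if mean == 0:
            break
        dev = np.abs(m - mean).max() / mean
        if dev < tol:
            converged = True
            break
        s = np.ones_like(marg)
        s[unm] = marg[unm] / mean
        s[s == 0] = 1.0
        bias *= np.sqrt(s)
        dense /= np.sqrt(np.outer(s, s))
    else:
        marg = dense.sum(axis=1)[unm]
        if marg.size and marg.mean() > 0:
            converged = np.abs(marg - marg.mean()).max() / marg.mean() < tol
    if not converged and unm.any():
        warnings.warn("iterative correction did not converge; result flagged unbalanced")
    out = ContactMatrix(
        matrix.bins,
        sp.csr_matrix(dense),
        balanced=converged,
        bias=bias,
        mask_zero_coverage=False,
    )
    return out


def expected_by_distance(matrix: ContactMatrix, chrom: str) -> np.ndarray:
    """Mean contact value at each bin separation within one chromosome.

    Average over unmasked bin pairs only; separations with no unmasked pair
    get NaN. Used to decay-normalize cis contact values (observed/expected).
    """
    lo, hi = matrix.bins.chrom_range(chrom)
    sub = matrix.values[lo:hi, lo:hi].toarray()
    unm = ~matrix.bins.mask[lo:hi]
    n = hi - lo
    exp = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(0, n - d)
        ok = unm[i] & unm[i + d]
        if ok.any():
            exp[d] = sub[i[ok], i[ok] + d].mean()
    return exp
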