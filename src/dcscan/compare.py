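"""Prediction-versus-experiment statistics.

Couplings predicted from sequence statistics (SCA cleaned matrix, DCA ddE
matrix) are compared with experimental coupling matrices by ordinary least
squares over the upper-triangle position pairs; significance of the
coefficient of determination r² comes from the F-test with F = r²(n−2)/(1−r²)
on (1, n−2) degrees of freedom under the no-correlation null.  Contact
prediction is scored as precision of the top-k ranked pairs against a contact
map (k = L/2 by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FitReport:
    slope: float
    intercept: float
    r2: float
    n: int
    f_statistic: float | None = None
    p_value: float | None = None


def linear_fit_r2(x, y) -> FitReport:
    """OLS fit y ~ x with r² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if np.ptp(y) == 0:
        warnings.warn("y is constant; r2 = 0", stacklevel=2)
        return FitReport(slope=0.0, intercept=float(y[0]), r2=0.0, n=len(x))
    res = stats.linregress(x, y)
    return FitReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(x),
    )


def f_test_p(r2: float, n: int) -> float:
    """Upper-tail F(1, n-2) probability for the observed r² (no-correlation null)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if r2 == 1.0:
        warnings.warn("r2 == 1: p-value is a 0 limit", stacklevel=2)
        return 0.0
    f = r2 * (n - 2) / (1.0 - r2)
    return float(stats.f.sf(f, 1, n - 2))


def fit_with_significance(x, y) -> FitReport:
    """OLS fit plus F-test significance of r²."""
    rep = linear_fit_r2(x, y)
    f = rep.r2 * (rep.n - 2) / (1.0 - rep.r2) if rep.r2 < 1 else np.inf
    return FitReport(
        slope=rep.slope,
        intercept=rep.intercept,
        r2=rep.r2,
        n=rep.n,
        f_statistic=float(f),
        p_value=f_test_p(rep.r2, rep.n),
    )


def matrix_pairs(*matrices: np.ndarray):
    """Upper-triangle entries shared (finite) across matrices, pairwise-dropped.

    Returns one aligned 1-D array per input matrix plus the (i, j) pair list
    (1-based).  This is the 36-pair comparison frame for a 9-position segment.
    """
    L = matrices[0].shape[0]
    iu, ju = np.triu_indices(L, k=1)
    cols = [m[iu, ju] for m in matrices]
    keep = np.all([np.isfinite(c) for c in cols], axis=0)
    pairs = [(int(i) + 1, int(j) + 1) for i, j in zip(iu[keep], ju[keep])]
    return [c[keep] for c in cols], pairs


def compare_matrices(pred: np.ndarray, exp: np.ndarray) -> FitReport:
    """Regress experimental couplings on predicted ones over shared pairs."""
    (x, y), _ = matrix_pairs(pred, exp)
    return fit_with_significance(x, y)


def contact_precision(ranked_pairs, contacts, k: int) -> float:
    """Fraction of the top-k ranked pairs present in the contact map."""
    contact_set = {(min(i, j), max(i, j)) for i, j in contacts}
    if not contact_set:
        raise ValueError("empty contact map")
    top = list(ranked_pairs)[:k]
    if len(top) < k:
        raise ValueError(f"ranking has fewer than k={k} pairs")
    hits = sum((min(i, j), max(i, j)) in contact_set for i, j in top)
    return hits / k
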