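"""Wilcoxon signed-rank helpers for the bin-wise population tests.

Two-tailed throughout; zero differences are dropped (Wilcoxon's original
handling).  Small tie-free samples (n <= 50 after dropping zeros) use
SciPy's exact null distribution.  Ties or larger samples use a normal
approximation with continuity correction whose variance is computed as
sum(r_i^2)/4 over the midranks — an identity that incorporates the tie
correction exactly (under H0, W+ = sum r_i B_i with B_i iid
Bernoulli(1/2), so Var = sum r_i^2 / 4) and vectorizes across time bins,
which keeps the bin-by-bin latency bootstrap fast.  (This mirrors the
exact-small / approximate-large split of the usual signed-rank
implementations.)
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["wsrt", "wsrt_columns"]

_EXACT_MAX_N = 50


def _approx_from_ranks(w_plus: float, ranks: np.ndarray) -> float:
    mu = float(np.sum(ranks)) / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wsrt(diffs: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test of ``diffs`` against zero.

    Returns ``(W+, p)`` with W+ the sum of ranks of positive differences.
    All-zero (or empty) input gives ``(0, 1)``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    if d.size <= _EXACT_MAX_N and np.unique(np.abs(d)).size == d.size:
        res = sps.wilcoxon(d, zero_method="wilcox",
                           alternative="two-sided", method="exact")
        return w_plus, float(res.pvalue)
    return w_plus, _approx_from_ranks(w_plus, ranks)


def wsrt_columns(d: np.ndarray, force_approx: bool = False) -> np.ndarray:
    """Column-wise two-tailed signed-rank p-values of an (n, m) matrix.

    Rows are paired observations (units), columns are time bins.  NaN rows
    are dropped per column.  Columns with <= 50 usable observations use
    SciPy (exact when tie-free); larger columns use the vectorized
    midrank normal approximation.  ``force_approx`` routes every column
    through the approximation (used by the bootstrap, where tens of
    thousands of column tests are recomputed per call).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2:
        raise ValueError("expected a 2-D (observations x bins) matrix")
    n, m = d.shape
    usable = np.isfinite(d) & (d != 0)
    absd = np.where(usable, np.abs(d), np.nan)
    ne = usable.sum(axis=0)
    p = np.ones(m)
    if n == 0 or m == 0:
        return p
    with np.errstate(invalid="ignore"):
        ranks = sps.rankdata(absd, axis=0, nan_policy="omit")
    ranks = np.where(usable, ranks, 0.0)
    w_plus = np.sum(ranks * (d > 0), axis=0)
    big = (ne > _EXACT_MAX_N) | (force_approx & (ne > 0))
    if np.any(big):
        mu = ranks.sum(axis=0) / 2.0
        var = np.sum(ranks ** 2, axis=0) / 4.0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        pb = 2.0 * sps.norm.sf(np.abs(z))
        p[big] = np.minimum(1.0, pb[big])
        p[big & (var <= 0)] = 1.0
    for j in np.flatnonzero(~big):
        if ne[j] == 0:
            p[j] = 1.0
            continue
        _, p[j] = wsrt(d[:, j])
    return p
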