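"""Relating the overall target-selection signal to the congruency effects.

The population-mean target-selection signal (all TarIn minus all DisIn
trials) is regressed on the population-mean NCE of target- or
distractor-role conditions, using the raw 10 ms bins between 200 and
1200 ms after cue onset (the 1000 ms following cue offset).  Because
adjacent 10 ms bins of a population mean are serially correlated, the
nominal p-value of the slope is optimistic; results carry a caveat flag
and the p-values are meant descriptively.

The two correlations (target vs distractor role) share the selection
series, so the default comparison bootstraps units: resample units with
replacement, rebuild all three population series, recompute r1 - r2, and
report the two-tailed bootstrap tail probability.  A Fisher-z comparison
(treating the correlations as independent) is available as a documented
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sps

from .congruency import EffectSeries

__all__ = ["RegressionResult", "CorrelationComparison",
           "nce_selection_regression", "compare_correlations",
           "REGRESSION_WINDOW"]

REGRESSION_WINDOW = (200.0, 1200.0)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n_bins: int
    window: Tuple[float, float]
    serial_correlation_caveat: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _window_bins(series: EffectSeries,
                 window: Tuple[float, float]) -> np.ndarray:
    edges = series.bin_left_edges
    return (edges >= window[0] - 1e-9) & (edges < window[1] - 1e-9)


def _pop_mean(mat: np.ndarray) -> np.ndarray:
    finite = np.isfinite(mat)
    n = finite.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(finite, mat, 0.0).sum(axis=0) / n
    return np.where(n == 0, np.nan, mean)


def nce_selection_regression(selection: EffectSeries, nce: EffectSeries,
                             window: Tuple[float, float] = REGRESSION_WINDOW
                             ) -> RegressionResult:
    """OLS of the population selection signal (y) on the population NCE (x).

    Both series must share the bin grid; raw (unsmoothed) 10 ms population
    means are used.  Zero variance in x is an error.
    """
    if selection.bin_centers.shape != nce.bin_centers.shape or \
            not np.allclose(selection.bin_centers, nce.bin_centers):
        raise ValueError("series are not on identical bin grids")
    keep = _window_bins(selection, window)
    y = _pop_mean(selection.unit_raw)[keep]
    x = _pop_mean(nce.unit_raw)[keep]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 usable bins in the window")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the NCE series over the window")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), r2=float(fit.rvalue ** 2),
                            p=float(fit.pvalue), n_bins=int(x.size),
                            window=window)


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    diff: float
    p: float
    method: str
    n_boot: int = 0
    seed: int = 0


def compare_correlations(selection: EffectSeries, nce1: EffectSeries,
                         nce2: EffectSeries,
                         window: Tuple[float, float] = REGRESSION_WINDOW,
                         method: str = "bootstrap", n_boot: int = 2000,
                         seed: int = 0) -> CorrelationComparison:
    """Compare corr(selection, nce1) with corr(selection, nce2).

    All three series must come from the same unit set (rows aligned), as
    they do when built from one selected population; the bootstrap then
    resamples that shared unit set.
    """
    for s in (nce1, nce2):
        if s.unit_raw.shape[0] != selection.unit_raw.shape[0]:
            raise ValueError("series have mismatched unit sets")
    keep = _window_bins(selection, window)

    def _r(sel_mat, mat) -> float:
        y = _pop_mean(sel_mat)[keep]
        x = _pop_mean(mat)[keep]
        ok = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    r1 = _r(selection.unit_raw, nce1.unit_raw)
    r2 = _r(selection.unit_raw, nce2.unit_raw)
    diff = r1 - r2
    if method == "fisher":
        n = int(keep.sum())
        z1, z2 = np.arctanh(np.clip([r1, r2], -0.999999, 0.999999))
        z = (z1 - z2) / np.sqrt(2.0 / (n - 3))
        p = float(2.0 * sps.norm.sf(abs(z)))
        return CorrelationComparison(r1, r2, diff, p, "fisher")
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'fisher'")
    n_units = selection.unit_raw.shape[0]
    if n_units < 10:
        raise ValueError("bootstrap comparison needs at least 10 units")
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        rows = rng.integers(0, n_units, size=n_units)
        diffs[b] = (_r(selection.unit_raw[rows], nce1.unit_raw[rows])
                    - _r(selection.unit_raw[rows], nce2.unit_raw[rows]))
    diffs = diffs[np.isfinite(diffs)]
    lo = float(np.mean(diffs <= 0))
    hi = float(np.mean(diffs >= 0))
    p = min(1.0, 2.0 * min(lo, hi))
    p = max(p, 1.0 / (diffs.size + 1))  # resolution floor of the bootstrap
    return CorrelationComparison(r1, r2, diff, p, "bootstrap", n_boot=n_boot,
                                 seed=seed)
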