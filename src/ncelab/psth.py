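"""Masked peri-stimulus time histograms.

Rates live on a fixed 10 ms grid aligned to cue onset.  Two exclusion rules
apply to every rate computation: the 200 ms following a distractor dimming
is masked out (the transient dimming response would otherwise contaminate
the delay-period rates), and each trial is truncated at target-dimming
onset.  Partial overlaps of a mask with a 10 ms bin are handled by
valid-time weighting: a bin's rate is total spikes in the valid part of the
bin across trials divided by the total valid time, so no bin is dropped or
zero-filled.  Cells with no valid time are NaN (missing).

Smoothing is a centered moving mean over the raw 10 ms bins: a width of
``w`` ms averages all bins whose centers lie within ±w/2 of the target bin
center (w = 100 gives an 11-bin window, w = 50 a 5-bin window).  Edge bins
average over the available part of the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import UnitSpikes
from .task import TaskTimeline, Trial, TrialCondition

__all__ = [
    "BIN_MS",
    "DEFAULT_RANGE",
    "DISTRACTOR_EXCLUSION_MS",
    "MaskedPSTH",
    "bin_edges",
    "trial_validity_mask",
    "valid_time_per_bin",
    "masked_spike_counts",
    "moving_mean",
    "condition_psth",
    "population_average",
    "cell",
    "condition_matches",
]

BIN_MS = 10.0
DEFAULT_RANGE = (-1700.0, 1600.0)
DISTRACTOR_EXCLUSION_MS = 200.0


def bin_edges(t_range: Tuple[float, float] = DEFAULT_RANGE,
              step: float = BIN_MS) -> np.ndarray:
    """Half-open bin edges [t, t+step) covering ``t_range``."""
    a, b = t_range
    n = int(round((b - a) / step))
    return a + step * np.arange(n + 1)


def _valid_intervals(timeline: TaskTimeline,
                     t_range: Tuple[float, float]) -> List[Tuple[float, float]]:
    """Intervals of valid analysis time for one trial within ``t_range``."""
    a = max(t_range[0], timeline.fixation_onset)
    b = min(t_range[1], timeline.target_dim_onset)
    if b <= a:
        return []
    if timeline.distractor_dim_onset is None:
        return [(a, b)]
    d0 = timeline.distractor_dim_onset
    d1 = d0 + DISTRACTOR_EXCLUSION_MS
    out = []
    if d0 > a:
        out.append((a, min(d0, b)))
    if d1 < b:
        out.append((max(d1, a), b))
    return [iv for iv in out if iv[1] > iv[0]]


def trial_validity_mask(timeline: TaskTimeline,
                        t_range: Tuple[float, float] = DEFAULT_RANGE
                        ) -> np.ndarray:
    """Per-millisecond validity over ``t_range``.

    False during [distractor_dim_onset, +200 ms) when a distractor dimming
    is present, false from target-dimming onset on, and false before the
    trial's fixation onset; true elsewhere.  Element ``i`` covers the
    millisecond [t_range[0] + i, t_range[0] + i + 1).
    """
    a, b = t_range
    n = int(round(b - a))
    mask = np.zeros(n, dtype=bool)
    for (lo, hi) in _valid_intervals(timeline, t_range):
        i0 = int(np.ceil(lo - a - 1e-9))
        i1 = int(np.floor(hi - a + 1e-9))
        # a millisecond counts as valid only if fully inside the interval
        i0 = max(i0, 0)
        i1 = min(i1, n)
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def valid_time_per_bin(timeline: TaskTimeline, edges: np.ndarray) -> np.ndarray:
    """Valid milliseconds contributed by one trial to each bin (exact)."""
    out = np.zeros(edges.size - 1)
    for (lo, hi) in _valid_intervals(timeline, (edges[0], edges[-1])):
        seg_lo = np.maximum(edges[:-1], lo)
        seg_hi = np.minimum(edges[1:], hi)
        out += np.clip(seg_hi - seg_lo, 0.0, None)
    return out


def masked_spike_counts(spikes: np.ndarray, timeline: TaskTimeline,
                        edges: np.ndarray) -> np.ndarray:
    """Spike counts per bin, counting only spikes in valid time."""
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        return np.zeros(edges.size - 1)
    keep = np.zeros(spikes.size, dtype=bool)
    for (lo, hi) in _valid_intervals(timeline, (edges[0], edges[-1])):
        keep |= (spikes >= lo) & (spikes < hi)
    counts, _ = np.histogram(spikes[keep], bins=edges)
    return counts.astype(float)


def moving_mean(x: np.ndarray, width: float, step: float = BIN_MS) -> np.ndarray:
    """Centered NaN-aware moving mean along the last axis.

    Window = all bins whose centers lie within ±width/2 of the output bin's
    center; edge bins use the available partial window.  ``width <= step``
    returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if width <= step:
        return x.copy()
    half = int(np.floor(width / 2.0 / step + 1e-9))
    if half == 0:
        return x.copy()
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    kernel = np.ones(2 * half + 1)
    # pad with zeros; counts track how many finite bins entered each window
    sums = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, vals)
    counts = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1,
        finite.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def cell(rule: Optional[str] = None, congruency: Optional[str] = None,
         target_side: Optional[str] = None) -> Dict[str, Optional[str]]:
    """Condition selector; ``None`` (or 'both') matches any level."""
    return {"rule": rule, "congruency": congruency, "target_side": target_side}


def condition_matches(cond: TrialCondition, selector: Dict[str, Optional[str]]) -> bool:
    for key, want in selector.items():
        if want is None or want == "both":
            continue
        if getattr(cond, key) != want:
            return False
    return True


@dataclass
class MaskedPSTH:
    """Units x conditions x bins rate array with valid-time weighting.

    ``rates`` are smoothed at ``width`` ms (``width = 0`` means raw 10 ms
    bins, also kept in ``raw_rates``).  ``valid_time`` is the summed valid
    milliseconds behind each raw cell; cells with zero valid time are NaN.
    """

    unit_ids: List[str]
    condition_labels: List[str]
    bin_centers: np.ndarray
    rates: np.ndarray
    raw_rates: np.ndarray
    valid_time: np.ndarray
    width: float
    step: float = BIN_MS

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: unit, condition, bin_center_ms, rate, valid."""
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for j, lab in enumerate(self.condition_labels):
                rows.append(pd.DataFrame({
                    "unit": uid, "condition": lab,
                    "bin_center_ms": self.bin_centers,
                    "rate": self.rates[i, j],
                    "raw_rate": self.raw_rates[i, j],
                    "valid_time_ms": self.valid_time[i, j]}))
        return pd.concat(rows, ignore_index=True)


def condition_psth(units: Sequence[UnitSpikes], trials: Sequence[Trial],
                   conditions: Dict[str, Dict[str, Optional[str]]],
                   width: float = 100.0, step: float = BIN_MS,
                   t_range: Tuple[float, float] = DEFAULT_RANGE,
                   hit_only: bool = True) -> MaskedPSTH:
    """Per-unit, per-condition masked PSTHs.

    ``conditions`` maps labels to selectors from :func:`cell`; each selector
    may pick one of the 8 task cells or any union (e.g. collapsing rule).
    Only hit trials enter by default.  A unit with zero valid trials for a
    condition gets a NaN row (missing, reported in the result).
    """
    edges = bin_edges(t_range, step)
    centers = 0.5 * (edges[:-1] + edges[1:])
    labels = list(conditions)
    trial_idx: Dict[str, np.ndarray] = {}
    for lab in labels:
        sel = [i for i, tr in enumerate(trials)
               if (not hit_only or tr.condition.outcome == "hit")
               and condition_matches(tr.condition, conditions[lab])]
        trial_idx[lab] = np.asarray(sel, dtype=int)
    # valid time per trial is unit independent: compute once
    vt_cache: Dict[int, np.ndarray] = {
        int(i): valid_time_per_bin(trials[int(i)].timeline, edges)
        for lab in labels for i in trial_idx[lab]}
    n_u, n_c, n_b = len(units), len(labels), centers.size
    raw = np.full((n_u, n_c, n_b), np.nan)
    vt = np.zeros((n_u, n_c, n_b))
    for ui, u in enumerate(units):
        for ci, lab in enumerate(labels):
            idx = trial_idx[lab]
            if idx.size == 0:
                continue
            counts = np.zeros(n_b)
            valid = np.zeros(n_b)
            for i in idx:
                counts += masked_spike_counts(u.spikes[int(i)],
                                              trials[int(i)].timeline, edges)
                valid += vt_cache[int(i)]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = 1000.0 * counts / valid
            r[valid == 0] = np.nan
            raw[ui, ci] = r
            vt[ui, ci] = valid
    rates = moving_mean(raw, width, step) if width > step else raw.copy()
    return MaskedPSTH(unit_ids=[u.unit_id for u in units],
                      condition_labels=labels, bin_centers=centers,
                      rates=rates, raw_rates=raw, valid_time=vt, width=width,
                      step=step)


def population_average(p: MaskedPSTH) -> pd.DataFrame:
    """Across-unit mean and s.e.m. per condition and bin.

    SE is sd / sqrt(n) over the units with data in that bin.
    """
    if len(p.unit_ids) < 2:
        raise ValueError("population average needs at least 2 units")
    rows = []
    for ci, lab in enumerate(p.condition_labels):
        x = p.rates[:, ci, :]
        finite = np.isfinite(x)
        n = finite.sum(axis=0)
        vals = np.where(finite, x, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = vals.sum(axis=0) / n
            var = (np.sum(vals ** 2, axis=0) - n * mean ** 2) / (n - 1)
            sem = np.sqrt(np.clip(var, 0.0, None)) / np.sqrt(n)
        mean = np.where(n == 0, np.nan, mean)
        sem = np.where(n <= 1, np.nan, sem)
        rows.append(pd.DataFrame({"condition": lab,
                                  "bin_center_ms": p.bin_centers,
                                  "mean_rate": mean, "sem": sem, "n_units": n}))
    return pd.concat(rows, ignore_index=True)
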