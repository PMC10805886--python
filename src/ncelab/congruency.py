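"""Congruency and target-selection contrasts, and modulation indices.

The neuronal congruency effect (NCE) is, per unit, the congruent-minus-
incongruent difference of masked PSTHs on the common 10 ms grid; the target
selection (spatial attention) signal is the TarIn-minus-DisIn difference,
where TarIn/DisIn denote trials with the target, respectively the
distractor, inside the unit's receptive field.  Population significance of
either contrast is a two-tailed Wilcoxon signed-rank test across units on
window means of the raw bins (50 ms windows stepped 10 ms for the NCE star
track, 100 ms for target selection, both configurable).

Modulation indices are normalized rate differences (A - B)/(A + B) computed
from raw spike counts over fixed windows (not from smoothed PSTHs):

* baseline variant: post-cue response (100-300 ms) against the 200 ms
  pre-cue baseline, per condition cell;
* congruency variant: congruent against incongruent response in one of the
  windows 0-200, 500-700 or 1000-1200 ms post cue, for target-role trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import UnitSpikes
from .psth import (
    BIN_MS,
    DEFAULT_RANGE,
    MaskedPSTH,
    cell,
    condition_psth,
    masked_spike_counts,
    moving_mean,
    valid_time_per_bin,
)
from .stats import wsrt, wsrt_columns
from .task import Trial

__all__ = [
    "EffectSeries",
    "ModulationIndex",
    "nce_series",
    "target_selection_series",
    "mi_baseline",
    "mi_congruency",
    "mi_population",
    "mi_congruency_tests",
    "MI_CONGRUENCY_WINDOWS",
]

logger = logging.getLogger(__name__)

MI_BASELINE_RESPONSE = (100.0, 300.0)
MI_BASELINE_BASE = (-200.0, 0.0)
MI_CONGRUENCY_WINDOWS = ((0.0, 200.0), (500.0, 700.0), (1000.0, 1200.0))


@dataclass
class EffectSeries:
    """A per-unit contrast time series with population summary and stars.

    ``unit_raw`` holds the raw 10 ms per-unit difference series (NaN where
    a unit lacks data); ``unit_smoothed`` the same smoothed at ``width``.
    ``p`` holds the two-tailed across-unit signed-rank p-value of the
    ``star_width`` window means, keyed to the same bin centers.
    """

    name: str
    unit_ids: List[str]
    bin_centers: np.ndarray
    unit_raw: np.ndarray
    unit_smoothed: np.ndarray
    pop_mean: np.ndarray
    pop_sem: np.ndarray
    p: np.ndarray
    width: float
    star_width: float
    alpha: float = 0.05

    @property
    def bin_left_edges(self) -> np.ndarray:
        return self.bin_centers - BIN_MS / 2.0

    @property
    def stars(self) -> np.ndarray:
        return self.p < self.alpha

    def negated(self) -> "EffectSeries":
        return EffectSeries(name=f"-({self.name})", unit_ids=self.unit_ids,
                            bin_centers=self.bin_centers,
                            unit_raw=-self.unit_raw,
                            unit_smoothed=-self.unit_smoothed,
                            pop_mean=-self.pop_mean, pop_sem=self.pop_sem,
                            p=self.p, width=self.width,
                            star_width=self.star_width, alpha=self.alpha)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_ms": self.bin_centers, "mean": self.pop_mean,
            "sem": self.pop_sem, "p": self.p, "star": self.stars})


def _pop_mean_sem(mat: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    finite = np.isfinite(mat)
    n = finite.sum(axis=0)
    vals = np.where(finite, mat, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = vals.sum(axis=0) / n
        var = (np.sum(vals ** 2, axis=0) - n * mean ** 2) / (n - 1)
        sem = np.sqrt(np.clip(var, 0.0, None)) / np.sqrt(n)
    return (np.where(n == 0, np.nan, mean), np.where(n <= 1, np.nan, sem))


def _difference_series(units: Sequence[UnitSpikes], trials: Sequence[Trial],
                       cond_a: Dict, cond_b: Dict, name: str, width: float,
                       star_width: float, t_range, alpha: float) -> EffectSeries:
    p = condition_psth(units, trials, {"a": cond_a, "b": cond_b}, width=0.0,
                       t_range=t_range)
    for lab, selector in (("a", cond_a), ("b", cond_b)):
        ci = p.condition_labels.index(lab)
        if not np.any(np.isfinite(p.raw_rates[:, ci, :])):
            raise ValueError(f"no trials for condition cell {selector} in {name}")
    raw = p.raw_rates[:, 0, :] - p.raw_rates[:, 1, :]
    missing = [uid for uid, row in zip(p.unit_ids, raw)
               if not np.any(np.isfinite(row))]
    if missing:
        logger.info("%s: units without data in both cells: %s", name, missing)
    smoothed = moving_mean(raw, width) if width > BIN_MS else raw.copy()
    star_means = moving_mean(raw, star_width) if star_width > BIN_MS else raw
    pvals = wsrt_columns(star_means)
    mean, sem = _pop_mean_sem(smoothed)
    return EffectSeries(name=name, unit_ids=list(p.unit_ids),
                        bin_centers=p.bin_centers, unit_raw=raw,
                        unit_smoothed=smoothed, pop_mean=mean, pop_sem=sem,
                        p=pvals, width=width, star_width=star_width,
                        alpha=alpha)


def nce_series(units: Sequence[UnitSpikes], trials: Sequence[Trial],
               role: str, rule: str = "both", width: float = 100.0,
               star_width: float = 50.0,
               t_range: Tuple[float, float] = DEFAULT_RANGE,
               alpha: float = 0.05) -> EffectSeries:
    """Congruent-minus-incongruent series for target- or distractor-role.

    ``role='target'`` fixes the target inside the RF (TarIn), ``'distractor'``
    outside (DisIn).  ``rule`` restricts to 'spatial' or 'color' trials or
    pools 'both'.  ``width=0`` leaves the display series unsmoothed (the
    latency analyses always use the raw per-unit series).
    """
    if role not in ("target", "distractor"):
        raise ValueError("role must be 'target' or 'distractor'")
    side = "in_rf" if role == "target" else "out_rf"
    r = None if rule == "both" else rule
    return _difference_series(
        units, trials, cell(rule=r, congruency="congruent", target_side=side),
        cell(rule=r, congruency="incongruent", target_side=side),
        name=f"NCE_{role}", width=width, star_width=star_width,
        t_range=t_range, alpha=alpha)


def target_selection_series(units: Sequence[UnitSpikes],
                            trials: Sequence[Trial],
                            congruency: str = "incongruent",
                            rule: str = "both", width: float = 100.0,
                            star_width: float = 100.0,
                            t_range: Tuple[float, float] = DEFAULT_RANGE,
                            alpha: float = 0.05) -> EffectSeries:
    """TarIn-minus-DisIn (attention) series within a congruency filter.

    ``congruency='all'`` pools both congruency levels (the overall target
    selection signal used in the regression analysis).
    """
    if congruency not in ("congruent", "incongruent", "all"):
        raise ValueError("congruency must be 'congruent', 'incongruent' or 'all'")
    cg = None if congruency == "all" else congruency
    r = None if rule == "both" else rule
    name = ("target_selection_overall" if congruency == "all"
            else f"target_selection_{congruency}")
    return _difference_series(
        units, trials, cell(rule=r, congruency=cg, target_side="in_rf"),
        cell(rule=r, congruency=cg, target_side="out_rf"),
        name=name, width=width, star_width=star_width, t_range=t_range,
        alpha=alpha)


@dataclass
class ModulationIndex:
    unit_id: str
    variant: str           # "baseline" or "congruency"
    window_label: str
    value: float           # (A - B)/(A + B), in [-1, 1]
    p: float               # per-unit significance (NaN when not defined)
    n_trials: int


def _window_rate(spikes: np.ndarray, trial: Trial,
                 window: Tuple[float, float]) -> Optional[float]:
    """Masked mean rate (sp/s) of one trial in a window; None if no valid time."""
    edges = np.asarray(window, dtype=float)
    valid = valid_time_per_bin(trial.timeline, edges)[0]
    if valid <= 0:
        return None
    count = masked_spike_counts(spikes, trial.timeline, edges)[0]
    return 1000.0 * count / valid


def mi_baseline(unit: UnitSpikes, trials: Sequence[Trial],
                condition: Dict[str, Optional[str]]) -> Optional[ModulationIndex]:
    """Baseline modulation index for one unit in one condition cell.

    MI = (R - R_b)/(R + R_b) with R the mean rate 100-300 ms post cue and
    R_b the mean rate over the 200 ms preceding the cue, across hit trials
    of the cell.  Per-unit significance is a two-tailed signed-rank test of
    the per-trial R - R_b differences.  Returns None (logged) when
    R + R_b = 0.
    """
    from .psth import condition_matches
    rs, rbs = [], []
    for tr, st in zip(trials, unit.spikes):
        if tr.condition.outcome != "hit" or not condition_matches(tr.condition,
                                                                  condition):
            continue
        r = _window_rate(st, tr, MI_BASELINE_RESPONSE)
        rb = _window_rate(st, tr, MI_BASELINE_BASE)
        if r is None or rb is None:
            continue
        rs.append(r)
        rbs.append(rb)
    if not rs:
        logger.info("mi_baseline: unit %s has no usable trials", unit.unit_id)
        return None
    r_mean, rb_mean = float(np.mean(rs)), float(np.mean(rbs))
    if r_mean + rb_mean == 0:
        logger.info("mi_baseline: unit %s excluded (zero rates)", unit.unit_id)
        return None
    _, p = wsrt(np.asarray(rs) - np.asarray(rbs))
    return ModulationIndex(unit_id=unit.unit_id, variant="baseline",
                           window_label="100-300ms_vs_baseline",
                           value=(r_mean - rb_mean) / (r_mean + rb_mean),
                           p=p, n_trials=len(rs))


def mi_congruency(unit: UnitSpikes, trials: Sequence[Trial],
                  window: Tuple[float, float], rule: str = "both"
                  ) -> Optional[ModulationIndex]:
    """Congruency modulation index for one target-role unit and window.

    MI = (R_con - R_incon)/(R_con + R_incon) on masked spike-count rates in
    ``window`` (one of 0-200, 500-700, 1000-1200 ms post cue, or any other
    window), over TarIn hit trials.  Per-unit p is a two-sample rank test
    between the congruent and incongruent per-trial rates (the two sets are
    distinct trials, so no pairing exists at unit level).
    """
    from .psth import condition_matches
    selector = cell(rule=None if rule == "both" else rule, target_side="in_rf")
    per_congr: Dict[str, List[float]] = {"congruent": [], "incongruent": []}
    for tr, st in zip(trials, unit.spikes):
        if tr.condition.outcome != "hit" or not condition_matches(tr.condition,
                                                                  selector):
            continue
        r = _window_rate(st, tr, window)
        if r is not None:
            per_congr[tr.condition.congruency].append(r)
    if not per_congr["congruent"] or not per_congr["incongruent"]:
        logger.info("mi_congruency: unit %s lacks a congruency level",
                    unit.unit_id)
        return None
    r_con = float(np.mean(per_congr["congruent"]))
    r_incon = float(np.mean(per_congr["incongruent"]))
    if r_con + r_incon == 0:
        logger.info("mi_congruency: unit %s excluded (zero rates)",
                    unit.unit_id)
        return None
    try:
        p = float(sps.mannwhitneyu(per_congr["congruent"],
                                   per_congr["incongruent"],
                                   alternative="two-sided").pvalue)
    except ValueError:
        p = float("nan")
    label = f"{int(window[0])}-{int(window[1])}ms"
    return ModulationIndex(unit_id=unit.unit_id, variant="congruency",
                           window_label=label,
                           value=(r_con - r_incon) / (r_con + r_incon), p=p,
                           n_trials=len(per_congr["congruent"])
                           + len(per_congr["incongruent"]))


def mi_population(units: Sequence[UnitSpikes], trials: Sequence[Trial],
                  variant: str, condition: Optional[Dict] = None,
                  window: Optional[Tuple[float, float]] = None,
                  rule: str = "both") -> pd.DataFrame:
    """Per-unit MI table plus the across-unit signed-rank test of median 0.

    For ``variant='baseline'`` supply a condition cell; for ``'congruency'``
    a window.  The returned frame carries the population p-value and median
    in its ``attrs``.
    """
    mis: List[ModulationIndex] = []
    for u in units:
        if variant == "baseline":
            if condition is None:
                raise ValueError("baseline MI needs a condition cell")
            mi = mi_baseline(u, trials, condition)
        elif variant == "congruency":
            if window is None:
                raise ValueError("congruency MI needs a window")
            mi = mi_congruency(u, trials, window, rule=rule)
        else:
            raise ValueError(f"unknown MI variant {variant!r}")
        if mi is not None:
            mis.append(mi)
    df = pd.DataFrame([vars(m) for m in mis])
    if len(df):
        _, pop_p = wsrt(df["value"].to_numpy())
        df.attrs["population_p"] = pop_p
        df.attrs["median"] = float(df["value"].median())
        df.attrs["n_significant"] = int((df["p"] < 0.05).sum())
    return df


def mi_congruency_tests(units: Sequence[UnitSpikes], trials: Sequence[Trial],
                        rule: str = "both",
                        windows=MI_CONGRUENCY_WINDOWS) -> pd.DataFrame:
    """Population congruency-MI tests for the three post-cue windows.

    Rows: one per window with the across-unit median and signed-rank p,
    plus paired t-tests of the first and last windows against the middle
    one (the U-shape contrast).
    """
    tables = {w: mi_population(units, trials, "congruency", window=w,
                               rule=rule) for w in windows}
    merged = None
    for w, tab in tables.items():
        lab = f"{int(w[0])}-{int(w[1])}"
        t = tab[["unit_id", "value"]].rename(columns={"value": lab})
        merged = t if merged is None else merged.merge(t, on="unit_id")
    rows = []
    labs = [f"{int(w[0])}-{int(w[1])}" for w in windows]
    for w, lab in zip(windows, labs):
        vals = merged[lab].to_numpy()
        _, p = wsrt(vals)
        row = {"window": lab, "median_mi": float(np.median(vals)),
               "mean_mi": float(np.mean(vals)), "wsrt_p": p,
               "n_units": vals.size, "t_vs_middle_p": np.nan}
        if lab != labs[1]:
            tt = sps.ttest_rel(vals, merged[labs[1]].to_numpy())
            row["t_vs_middle_p"] = float(tt.pvalue)
            row["t_vs_middle_stat"] = float(tt.statistic)
        rows.append(row)
    return pd.DataFrame(rows)
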