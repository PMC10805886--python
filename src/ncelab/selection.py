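"""Two-stage unit inclusion: visually driven, then contralateral RF.

Stage 1 keeps units whose response in the 500 ms following the onset of
the two peripheral stimuli exceeds the 200-500 ms post-fixation-onset
baseline (two-tailed paired t-test across hit trials, p < 0.05, with the
stimulus-window mean the larger).  Stage 2 keeps units responding more to
target dimming in the contralateral (in-RF) than the ipsilateral hemifield
(rate 50-200 ms after dimming onset; p < 0.05 and directionally correct).

The hemifield comparison involves two disjoint trial sets, so the default
test is a two-sample Welch t-test; ``rf_method='paired'`` pairs trials by
task order instead (truncating to the shorter set) for a literal
paired-test reading.  No multiple-testing correction is applied across
units.  Rates are spike count / window length; empty windows contribute
0 sp/s.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SelectionResult, SessionData, UnitSpikes
from .task import FIXATION_ONSET, STIMULI_ONSET, Trial

__all__ = ["visually_driven_test", "contralateral_rf_test", "select_units"]

ALPHA = 0.05
STIM_WINDOW = (STIMULI_ONSET, STIMULI_ONSET + 500.0)        # [-600, -100)
FIX_WINDOW = (FIXATION_ONSET + 200.0, FIXATION_ONSET + 500.0)  # [-1400, -1100)
DIM_WINDOW = (50.0, 200.0)  # relative to target-dimming onset


def _window_rate(spikes: np.ndarray, lo: float, hi: float) -> float:
    spikes = np.asarray(spikes, dtype=float)
    n = int(np.count_nonzero((spikes >= lo) & (spikes < hi)))
    return 1000.0 * n / (hi - lo)


def visually_driven_test(unit: UnitSpikes, trials: Sequence[Trial],
                         alpha: float = ALPHA) -> SelectionResult:
    """Stage-1 test: stimulus-evoked response above pre-stimulus baseline."""
    stim, base = [], []
    for tr, st in zip(trials, unit.spikes):
        if tr.condition.outcome != "hit":
            continue
        stim.append(_window_rate(st, *STIM_WINDOW))
        base.append(_window_rate(st, *FIX_WINDOW))
    if len(stim) < 2:
        return SelectionResult(np.nan, np.nan, False, untestable=True,
                               note="fewer than 2 usable trials")
    stim_a, base_a = np.asarray(stim), np.asarray(base)
    if np.allclose(stim_a, base_a):
        return SelectionResult(0.0, 1.0, False,
                               note="identical rates in both windows")
    t, p = sps.ttest_rel(stim_a, base_a)
    if not np.isfinite(p):
        return SelectionResult(float(t) if np.isfinite(t) else np.nan, np.nan,
                               False, untestable=True,
                               note="degenerate paired t-test")
    passed = bool(p < alpha and stim_a.mean() > base_a.mean())
    return SelectionResult(float(t), float(p), passed)


def contralateral_rf_test(unit: UnitSpikes, trials: Sequence[Trial],
                          alpha: float = ALPHA, method: str = "welch"
                          ) -> SelectionResult:
    """Stage-2 test: stronger target-dimming response for in-RF targets."""
    groups = {"in_rf": [], "out_rf": []}
    for tr, st in zip(trials, unit.spikes):
        if tr.condition.outcome != "hit":
            continue
        td = tr.timeline.target_dim_onset
        rate = _window_rate(st, td + DIM_WINDOW[0], td + DIM_WINDOW[1])
        groups[tr.condition.target_side].append(rate)
    a = np.asarray(groups["in_rf"], dtype=float)
    b = np.asarray(groups["out_rf"], dtype=float)
    if a.size < 2 or b.size < 2:
        return SelectionResult(np.nan, np.nan, False, untestable=True,
                               note="a hemifield has fewer than 2 trials")
    if method == "welch":
        t, p = sps.ttest_ind(a, b, equal_var=False)
    elif method == "paired":
        k = min(a.size, b.size)
        t, p = sps.ttest_rel(a[:k], b[:k])
    else:
        raise ValueError("method must be 'welch' or 'paired'")
    if not np.isfinite(p):
        return SelectionResult(np.nan, np.nan, False, untestable=True,
                               note="degenerate test (e.g. no spikes)")
    passed = bool(p < alpha and a.mean() > b.mean())
    return SelectionResult(float(t), float(p), passed)


def select_units(session: SessionData, alpha: float = ALPHA,
                 rf_method: str = "welch") -> Tuple[list, pd.DataFrame]:
    """Run both inclusion tests on every unit of a session.

    Returns the ids passing both stages and a per-unit report
    (stage statistics, p-values, pass flags, inclusion).  Results are also
    attached to each unit's ``selection`` dict.  Selection is independent
    of unit order.
    """
    rows = []
    included = []
    for u in session.units:
        vis = visually_driven_test(u, session.trials, alpha=alpha)
        rf = contralateral_rf_test(u, session.trials, alpha=alpha,
                                   method=rf_method)
        u.selection["visually_driven"] = vis
        u.selection["contralateral_rf"] = rf
        ok = vis.passed and rf.passed
        if ok:
            included.append(u.unit_id)
        rows.append({
            "session_id": session.session_id,
            "subject_id": session.subject_id,
            "unit_id": u.unit_id,
            "stage1_stat": vis.statistic, "stage1_p": vis.p,
            "stage1_pass": vis.passed, "stage1_untestable": vis.untestable,
            "stage2_stat": rf.statistic, "stage2_p": rf.p,
            "stage2_pass": rf.passed, "stage2_untestable": rf.untestable,
            "included": ok,
        })
    report = pd.DataFrame(rows)
    report.attrs["n_total"] = len(session.units)
    report.attrs["n_stage1"] = int(report["stage1_pass"].sum())
    report.attrs["n_included"] = len(included)
    return included, report
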