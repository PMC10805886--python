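"""Session-level behavioral congruency statistics.

Accuracy per session and congruency is hits / (hits + false alarms +
misses); fixation-break trials never enter the denominator.  RT is the
button press time minus target-dimming onset (valid hits fall in the
200-700 ms response window) and is summarized per session by the mean over
hit trials (median also reported).  The congruency effect is assessed per
subject with a two-tailed paired t-test across sessions, congruent versus
incongruent, separately for accuracy and RT.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SessionData
from .task import CONGRUENCIES

__all__ = ["session_performance", "behavior_summary", "congruency_ttests"]

logger = logging.getLogger(__name__)


def session_performance(session: SessionData) -> pd.DataFrame:
    """Per-congruency accuracy and RT summary for one session."""
    tab = session.behavior_table()
    rows = []
    for congr in CONGRUENCIES:
        sub = tab[tab["congruency"] == congr]
        n_hit = int(sub["n_hit"].sum())
        n_err = int(sub["n_false_alarm"].sum() + sub["n_miss"].sum())
        if n_hit + n_err == 0:
            logger.info("session %s/%s: no scored trials", session.session_id,
                        congr)
            acc = np.nan
        else:
            acc = n_hit / (n_hit + n_err)
        rts = []
        for tr in session.trials:
            if (tr.condition.congruency == congr
                    and tr.condition.outcome == "hit"
                    and tr.timeline.response_time is not None):
                rts.append(tr.timeline.response_time
                           - tr.timeline.target_dim_onset)
        rows.append({
            "session_id": session.session_id,
            "subject_id": session.subject_id,
            "congruency": congr, "n_hit": n_hit, "n_error": n_err,
            "n_fixation_break": int(sub["n_fixation_break"].sum()),
            "accuracy": acc,
            "mean_rt": float(np.mean(rts)) if rts else np.nan,
            "median_rt": float(np.median(rts)) if rts else np.nan,
        })
    return pd.DataFrame(rows)


def behavior_summary(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Stack per-session performance tables for a cohort."""
    return pd.concat([session_performance(s) for s in sessions],
                     ignore_index=True)


def congruency_ttests(sessions: Sequence[SessionData],
                      rt_summary: str = "mean_rt") -> pd.DataFrame:
    """Paired t-tests of the behavioral congruency effect, per subject.

    Needs >= 2 sessions per subject; each session must contribute both
    congruency levels.  Returns one row per (subject, measure) with the t
    statistic, dof, p-value and the two condition means.
    """
    if rt_summary not in ("mean_rt", "median_rt"):
        raise ValueError("rt_summary must be 'mean_rt' or 'median_rt'")
    summary = behavior_summary(sessions)
    rows = []
    for subject, sub in summary.groupby("subject_id", sort=True):
        wide_acc = sub.pivot_table(index="session_id", columns="congruency",
                                   values="accuracy")
        wide_rt = sub.pivot_table(index="session_id", columns="congruency",
                                  values=rt_summary)
        for wide, measure in ((wide_acc, "accuracy"), (wide_rt, "rt")):
            if set(wide.columns) != set(CONGRUENCIES) or wide.isna().any().any():
                raise ValueError(
                    f"subject {subject}: unmatched congruent/incongruent "
                    f"session sets for {measure}")
            if len(wide) < 2:
                raise ValueError(f"subject {subject}: fewer than 2 sessions")
            con = wide["congruent"].to_numpy()
            incon = wide["incongruent"].to_numpy()
            if np.allclose(con, incon):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(con, incon)
            rows.append({
                "subject_id": subject, "measure": measure,
                "n_sessions": len(wide), "mean_congruent": float(con.mean()),
                "mean_incongruent": float(incon.mean()),
                "t": float(t), "dof": len(wide) - 1, "p": float(p),
            })
    return pd.DataFrame(rows)
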