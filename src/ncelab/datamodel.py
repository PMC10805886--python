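"""In-memory session containers: trials, per-unit spike trains, behavior."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .task import Trial

__all__ = ["SelectionResult", "UnitSpikes", "SessionData"]


@dataclass
class SelectionResult:
    """Outcome of one unit-inclusion test."""

    statistic: float
    p: float
    passed: bool
    untestable: bool = False
    note: str = ""


@dataclass
class UnitSpikes:
    """One unit's spike timestamps, stored per trial.

    Timestamps are in ms, referenced to cue onset, strictly sorted within
    each trial.  ``selection`` holds the results of the inclusion tests once
    the selection stage has run (absent before that).
    """

    unit_id: str
    channel: int
    spikes: List[np.ndarray]
    selection: Dict[str, SelectionResult] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    def validate(self, trials: Optional[Sequence[Trial]] = None) -> None:
        if trials is not None and len(self.spikes) != len(trials):
            raise ValueError(
                f"unit {self.unit_id}: {len(self.spikes)} spike lists for "
                f"{len(trials)} trials"
            )
        for i, st in enumerate(self.spikes):
            st = np.asarray(st, dtype=float)
            if st.ndim != 1:
                raise ValueError(f"unit {self.unit_id}: trial {i} spikes not 1-D")
            if st.size > 1 and not np.all(np.diff(st) > 0):
                raise ValueError(
                    f"unit {self.unit_id}: trial {i} spike times not strictly sorted"
                )
            if trials is not None and st.size:
                tl = trials[i].timeline
                if st[0] < tl.fixation_onset or st[-1] > tl.trial_end:
                    raise ValueError(
                        f"unit {self.unit_id}: trial {i} spikes outside "
                        f"[{tl.fixation_onset}, {tl.trial_end}] ms"
                    )


@dataclass
class SessionData:
    """One recording (or simulated) session.

    Attributes
    ----------
    session_id, subject_id : str
        Identifiers; ``subject_id`` must be one of ``subjects``.
    trials : list of Trial
        Timeline plus condition labels, one per trial, in task order.
    units : list of UnitSpikes
        Per-unit spike trains aligned to ``trials``.
    subjects : tuple of str
        The subjects declared for the study this session belongs to.
    meta : dict
        Free-form provenance (generator seed, config hash, ...).
    """

    session_id: str
    subject_id: str
    trials: List[Trial]
    units: List[UnitSpikes]
    subjects: tuple = ("S", "R")
    meta: Dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if self.subject_id not in self.subjects:
            raise ValueError(
                f"subject_id {self.subject_id!r} not in declared subjects "
                f"{self.subjects}"
            )
        for t in self.trials:
            t.validate()
        for u in self.units:
            u.validate(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def condition_table(self) -> pd.DataFrame:
        """Trials as a flat table (one row per trial)."""
        rows = []
        for i, tr in enumerate(self.trials):
            c, tl = tr.condition, tr.timeline
            rows.append({
                "trial": i,
                "rule": c.rule,
                "congruency": c.congruency,
                "target_side": c.target_side,
                "cue_side": c.cue_side,
                "cue_color": c.cue_color,
                "outcome": c.outcome,
                "distractor_dim_onset": tl.distractor_dim_onset,
                "target_dim_onset": tl.target_dim_onset,
                "response_time": tl.response_time,
                "trial_end": tl.trial_end,
            })
        return pd.DataFrame(rows)

    def behavior_table(self) -> pd.DataFrame:
        """Per (rule, congruency) outcome counts and hit reaction times.

        RT is response time minus target-dimming onset (ms).  Fixation-break
        trials are tallied but never enter accuracy or RT summaries.
        """
        tab = self.condition_table()
        tab["rt"] = tab["response_time"] - tab["target_dim_onset"]
        rows = []
        for (rule, congr), grp in tab.groupby(["rule", "congruency"], sort=True):
            rts = grp.loc[grp["outcome"] == "hit", "rt"].dropna().to_numpy()
            rows.append({
                "session_id": self.session_id,
                "subject_id": self.subject_id,
                "rule": rule,
                "congruency": congr,
                "n_hit": int((grp["outcome"] == "hit").sum()),
                "n_false_alarm": int((grp["outcome"] == "false_alarm").sum()),
                "n_miss": int((grp["outcome"] == "miss").sum()),
                "n_fixation_break": int((grp["outcome"] == "fixation_break").sum()),
                "mean_rt": float(np.mean(rts)) if rts.size else np.nan,
                "median_rt": float(np.median(rts)) if rts.size else np.nan,
            })
        return pd.DataFrame(rows)

    def hit_trial_indices(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.trials) if t.condition.outcome == "hit"],
            dtype=int,
        )
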