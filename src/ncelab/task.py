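"""Task structure: trial timelines and condition labels.

The task is a rule-switching covert-attention paradigm. A trial starts with
fixation, a rule cue (horizontal bar = color rule, vertical bar = spatial
rule), then two peripheral white squares appear; 600 ms later one square
turns red or pink for 200 ms (the color cue). Under the spatial rule the
cue's location indicates the target, under the color rule its color does
(red = left, pink = right). Congruent trials are those in which location and
color point to the same side. The animal responds to a brief dimming of the
target while ignoring an optional earlier dimming of the distractor.

All times are in milliseconds, referenced to color-cue onset (t = 0).
The recorded hemisphere is the right one, so ``in_rf`` denotes the left
(contralateral) hemifield.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "TaskTimeline",
    "TrialCondition",
    "Trial",
    "condition_cell",
    "RULES",
    "CONGRUENCIES",
    "SIDES",
    "OUTCOMES",
    "FIXATION_ONSET",
    "RULE_CUE_ONSET",
    "RULE_CUE_OFFSET",
    "STIMULI_ONSET",
    "CUE_ONSET",
    "CUE_OFFSET",
    "TARGET_DIM_RANGE",
    "DISTRACTOR_DIM_RANGE",
    "MIN_DIM_SEPARATION",
    "RESPONSE_WINDOW",
]

RULES = ("spatial", "color")
CONGRUENCIES = ("congruent", "incongruent")
SIDES = ("in_rf", "out_rf")
OUTCOMES = ("hit", "false_alarm", "miss", "fixation_break")

# Fixed event times (ms, cue-onset referenced).
FIXATION_ONSET = -1600.0
RULE_CUE_ONSET = -1100.0
RULE_CUE_OFFSET = -600.0
STIMULI_ONSET = -600.0
CUE_ONSET = 0.0
CUE_OFFSET = 200.0

# Jittered event windows (ms after cue onset).  Target dimming occurs
# 660-1950 ms after cue offset; distractor dimming (50% of trials)
# 200-1500 ms after cue offset and at least 300 ms before target dimming.
TARGET_DIM_RANGE = (860.0, 2150.0)
DISTRACTOR_DIM_RANGE = (400.0, 1700.0)
MIN_DIM_SEPARATION = 300.0
# Button press counts as a hit when it falls 200-700 ms after target dimming.
RESPONSE_WINDOW = (200.0, 700.0)


@dataclass(frozen=True)
class TaskTimeline:
    """Event times of one trial in ms, referenced to color-cue onset."""

    fixation_onset: float = FIXATION_ONSET
    rule_cue_onset: float = RULE_CUE_ONSET
    rule_cue_offset: float = RULE_CUE_OFFSET
    stimuli_onset: float = STIMULI_ONSET
    cue_onset: float = CUE_ONSET
    cue_offset: float = CUE_OFFSET
    distractor_dim_onset: Optional[float] = None
    target_dim_onset: float = 1500.0
    response_time: Optional[float] = None
    trial_end: float = 2200.0

    def validate(self) -> None:
        if self.cue_onset != 0.0:
            raise ValueError("cue_onset must be 0 (session reference)")
        if self.cue_offset - self.cue_onset != 200.0:
            raise ValueError("cue_offset must be cue_onset + 200 ms")
        if self.stimuli_onset != STIMULI_ONSET:
            raise ValueError("stimuli_onset must be -600 ms")
        if self.rule_cue_onset != RULE_CUE_ONSET or self.rule_cue_offset != RULE_CUE_OFFSET:
            raise ValueError("rule cue must span [-1100, -600] ms")
        lo, hi = TARGET_DIM_RANGE
        if not (lo <= self.target_dim_onset <= hi):
            raise ValueError(
                f"target_dim_onset {self.target_dim_onset} outside [{lo}, {hi}] ms"
            )
        if self.distractor_dim_onset is not None:
            dlo, dhi = DISTRACTOR_DIM_RANGE
            if not (dlo <= self.distractor_dim_onset <= dhi):
                raise ValueError(
                    f"distractor_dim_onset {self.distractor_dim_onset} outside "
                    f"[{dlo}, {dhi}] ms"
                )
            if self.distractor_dim_onset > self.target_dim_onset - MIN_DIM_SEPARATION:
                raise ValueError(
                    "distractor dimming must precede target dimming by >= 300 ms"
                )
        if self.trial_end < self.target_dim_onset:
            raise ValueError("trial_end precedes target_dim_onset")


@dataclass(frozen=True)
class TrialCondition:
    """Condition labels of one trial.

    ``congruency`` is fully determined by (cue_color, cue_side): red in the
    left (in-RF) hemifield or pink in the right one is congruent, the
    reverse is incongruent.  ``target_side`` follows from the rule: under the
    spatial rule the target is at the cue's location, under the color rule
    red places it left (in RF) and pink right.
    """

    rule: str
    congruency: str
    target_side: str
    cue_side: str
    cue_color: str
    outcome: str = "hit"

    def validate(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.congruency not in CONGRUENCIES:
            raise ValueError(f"unknown congruency {self.congruency!r}")
        for name, side in (("target_side", self.target_side), ("cue_side", self.cue_side)):
            if side not in SIDES:
                raise ValueError(f"unknown {name} {side!r}")
        if self.cue_color not in ("red", "pink"):
            raise ValueError(f"unknown cue_color {self.cue_color!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        # congruency from (color, side): red-left / pink-right => congruent
        congruent = (self.cue_color == "red") == (self.cue_side == "in_rf")
        if (self.congruency == "congruent") != congruent:
            raise ValueError("congruency inconsistent with cue color and side")
        # target side from rule
        if self.rule == "spatial":
            expected = self.cue_side
        else:
            expected = "in_rf" if self.cue_color == "red" else "out_rf"
        if self.target_side != expected:
            raise ValueError("target_side inconsistent with rule and cue")


@dataclass(frozen=True)
class Trial:
    """One trial: its timeline and condition labels."""

    timeline: TaskTimeline
    condition: TrialCondition

    def validate(self) -> None:
        self.timeline.validate()
        self.condition.validate()


def condition_cell(rule: str, congruency: str, target_side: str,
                   outcome: str = "hit") -> TrialCondition:
    """Build the unique TrialCondition for one of the 8 task cells.

    The cue's side and color are derived from (rule, congruency,
    target_side) by inverting the task mapping, so the returned condition
    always satisfies the congruency and rule invariants.
    """
    if rule == "spatial":
        cue_side = target_side
        # congruent: red-left / pink-right
        if congruency == "congruent":
            cue_color = "red" if cue_side == "in_rf" else "pink"
        else:
            cue_color = "pink" if cue_side == "in_rf" else "red"
    elif rule == "color":
        cue_color = "red" if target_side == "in_rf" else "pink"
        matched_side = "in_rf" if cue_color == "red" else "out_rf"
        if congruency == "congruent":
            cue_side = matched_side
        else:
            cue_side = "out_rf" if matched_side == "in_rf" else "in_rf"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    cond = TrialCondition(rule=rule, congruency=congruency,
                          target_side=target_side, cue_side=cue_side,
                          cue_color=cue_color, outcome=outcome)
    cond.validate()
    return cond
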