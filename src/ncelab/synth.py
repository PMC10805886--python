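"""Synthetic sessions: trials, inhomogeneous-Poisson spike trains, behavior.

The generator emulates the statistical structure the downstream analysis
assumes for visually driven, contralateral-RF units in FEF during the
rule-switching conflict task:

* a condition-independent response before cue onset (baseline, then a
  sustained visual response to the two white squares);
* a brief multiplicative transient when the color cue falls inside the RF;
* from a configurable congruency-onset latency, distractor-role conditions
  (target outside the RF) are suppressed in congruent and enhanced in
  incongruent trials, producing a persistent negative congruency effect;
* target-role conditions carry a signed three-window (U-shaped) congruency
  effect on top of the enhanced incongruent level;
* in incongruent trials the target-role response ramps up from a
  configurable resolution latency, so the target-minus-distractor
  (attention) signal is zero until then and rises only after it, while the
  distractor-role congruency effect stays flat (persistent);
* a transient response to the dimming of the in-RF stimulus, which drives
  the receptive-field inclusion test and motivates the post-dimming
  exclusion mask.

Firing rates are piecewise constant (the resolution ramp is staircased at
10 ms), which allows exact inhomogeneous-Poisson sampling segment by
segment: counts are Poisson with mean rate x duration and spike times are
uniform within each segment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .datamodel import SessionData, UnitSpikes
from .task import (
    CONGRUENCIES,
    DISTRACTOR_DIM_RANGE,
    FIXATION_ONSET,
    MIN_DIM_SEPARATION,
    RESPONSE_WINDOW,
    RULES,
    SIDES,
    STIMULI_ONSET,
    TARGET_DIM_RANGE,
    TaskTimeline,
    Trial,
    TrialCondition,
    condition_cell,
)

__all__ = [
    "PiecewiseRate",
    "RateProfileParams",
    "ParamDistributions",
    "SynthConfig",
    "rate_profile",
    "sample_spikes",
    "generate_behavior",
    "generate_session",
    "generate_sessions",
]

# Signed congruency-effect windows for target-role conditions (ms post cue).
U_SHAPE_WINDOWS = ((0.0, 200.0), (300.0, 750.0), (750.0, 1600.0))
# Cue-in-RF visual transient (ms post cue).
CUE_TRANSIENT_WINDOW = (60.0, 200.0)
# Dimming transient window relative to dim onset (ms); chosen to match the
# 50-200 ms read-out window of the RF test.
DIM_TRANSIENT_WINDOW = (50.0, 200.0)


class PiecewiseRate:
    """Piecewise-constant firing rate (sp/s) over [edges[0], edges[-1]] ms.

    Zero outside its support.  Supports exact integration and exact
    inhomogeneous-Poisson sampling.
    """

    def __init__(self, edges: np.ndarray, rates: np.ndarray):
        edges = np.asarray(edges, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if edges.ndim != 1 or rates.ndim != 1 or edges.size != rates.size + 1:
            raise ValueError("edges must have one more element than rates")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite and non-negative")
        self.edges = edges
        self.rates = rates

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1,
                      0, self.rates.size - 1)
        out = self.rates[idx]
        out = np.where((t < self.edges[0]) | (t >= self.edges[-1]), 0.0, out)
        return out if out.ndim else float(out)

    def integral(self, a: float, b: float) -> float:
        """Integral of the rate over [a, b] in spikes (ms rates / 1000)."""
        lo = np.maximum(self.edges[:-1], a)
        hi = np.minimum(self.edges[1:], b)
        dur = np.clip(hi - lo, 0.0, None)
        return float(np.sum(dur * self.rates) / 1000.0)

    def scaled(self, gain: float) -> "PiecewiseRate":
        return PiecewiseRate(self.edges, self.rates * gain)

    @property
    def max_rate(self) -> float:
        return float(self.rates.max()) if self.rates.size else 0.0


@dataclass(frozen=True)
class RateProfileParams:
    """Per-unit rate-profile parameters (rates in sp/s, latencies in ms)."""

    baseline_rate: float = 10.0
    visual_response_rate: float = 25.0
    visual_latency: float = 70.0
    cue_transient_gain: float = 1.3
    nce_onset_latency: float = 90.0
    distractor_suppression: float = 0.3
    distractor_enhancement: float = 0.3
    target_u_shape: Tuple[float, float, float] = (3.0, -3.0, 11.0)
    resolution_latency: float = 600.0
    selection_amplitude: float = 8.0
    selection_ramp_ms: float = 300.0
    dim_transient_rate: float = 15.0
    noise_cv: float = 0.2

    def validate(self) -> None:
        for name in ("baseline_rate", "visual_response_rate",
                     "dim_transient_rate", "selection_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("visual_latency", "nce_onset_latency",
                     "resolution_latency", "selection_ramp_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("distractor_suppression", "distractor_enhancement"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.cue_transient_gain < 0:
            raise ValueError("cue_transient_gain must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def rate_profile(params: RateProfileParams, cond: TrialCondition,
                 timeline: TaskTimeline) -> PiecewiseRate:
    """Build the piecewise firing-rate profile for one trial.

    Before ``cue_onset + nce_onset_latency`` the profile depends on
    congruency only through the cue-in-RF visual transient (which differs
    between congruency levels only under the color rule, where the cue side
    flips); with ``cue_transient_gain = 1`` the profile is congruency
    invariant up to the congruency-onset latency, and it is always
    congruency invariant before cue onset.
    """
    params.validate()
    p = params
    tl = timeline
    t0, t1 = tl.fixation_onset, tl.trial_end
    vis_on = STIMULI_ONSET + p.visual_latency
    nce_on = p.nce_onset_latency
    dis_role = cond.target_side == "out_rf"
    incongruent = cond.congruency == "incongruent"

    breaks = {t0, t1, vis_on, nce_on}
    if cond.cue_side == "in_rf" and p.cue_transient_gain != 1.0:
        breaks.update(CUE_TRANSIENT_WINDOW)
    if not dis_role:
        for (a, b) in U_SHAPE_WINDOWS:
            breaks.update((max(a, nce_on), max(b, nce_on)))
    ramp_active = (not dis_role) and incongruent and p.selection_amplitude > 0
    if ramp_active:
        # staircase the linear ramp at 10 ms resolution
        n_steps = max(1, int(np.ceil(p.selection_ramp_ms / 10.0)))
        for k in range(n_steps + 1):
            breaks.add(p.resolution_latency + 10.0 * k)
    dim_windows = []
    if not dis_role:
        dim_windows.append((tl.target_dim_onset + DIM_TRANSIENT_WINDOW[0],
                            tl.target_dim_onset + DIM_TRANSIENT_WINDOW[1]))
    elif tl.distractor_dim_onset is not None:
        dim_windows.append((tl.distractor_dim_onset + DIM_TRANSIENT_WINDOW[0],
                            tl.distractor_dim_onset + DIM_TRANSIENT_WINDOW[1]))
    for (a, b) in dim_windows:
        breaks.update((a, b))

    edges = np.array(sorted(b for b in breaks if t0 <= b <= t1))
    if edges[0] > t0:
        edges = np.concatenate(([t0], edges))
    if edges[-1] < t1:
        edges = np.concatenate((edges, [t1]))
    mids = 0.5 * (edges[:-1] + edges[1:])

    rates = np.where(mids < vis_on, p.baseline_rate, p.visual_response_rate)
    if cond.cue_side == "in_rf":
        in_tr = (mids >= CUE_TRANSIENT_WINDOW[0]) & (mids < CUE_TRANSIENT_WINDOW[1])
        rates = np.where(in_tr, rates * p.cue_transient_gain, rates)
    post = mids >= nce_on
    if dis_role:
        factor = (1.0 + p.distractor_enhancement) if incongruent \
            else (1.0 - p.distractor_suppression)
        rates = np.where(post, rates * factor, rates)
    else:
        rates = np.where(post, rates * (1.0 + p.distractor_enhancement), rates)
        if incongruent:
            if ramp_active:
                frac = np.clip(
                    (np.floor((mids - p.resolution_latency) / 10.0) * 10.0
                     + 5.0) / max(p.selection_ramp_ms, 10.0), 0.0, 1.0)
                ramp = np.where(mids >= p.resolution_latency,
                                p.selection_amplitude * frac, 0.0)
                rates = rates + ramp
        else:
            for (a, b), amp in zip(U_SHAPE_WINDOWS, p.target_u_shape):
                in_w = post & (mids >= a) & (mids < b)
                rates = np.where(in_w, rates + amp, rates)
    for (a, b) in dim_windows:
        in_d = (mids >= a) & (mids < b)
        rates = np.where(in_d, rates + p.dim_transient_rate, rates)

    return PiecewiseRate(edges, np.clip(rates, 0.0, None))


def sample_spikes(rate_fn, t_range: Tuple[float, float],
                  seed: Union[int, np.random.Generator]) -> np.ndarray:
    """Sample an inhomogeneous Poisson spike train on ``t_range`` (ms).

    Piecewise-constant rates are sampled exactly (Poisson counts per
    segment, uniform times within segments).  A generic callable rate is
    discretized on a 1 ms grid.  Negative or non-finite rates are rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    a, b = float(t_range[0]), float(t_range[1])
    if b <= a:
        return np.empty(0, dtype=float)
    if isinstance(rate_fn, PiecewiseRate):
        lo = np.maximum(rate_fn.edges[:-1], a)
        hi = np.minimum(rate_fn.edges[1:], b)
        dur = np.clip(hi - lo, 0.0, None)
        lam = rate_fn.rates * dur / 1000.0
    else:
        grid = np.arange(a, b, 1.0)
        lo = grid
        dur = np.minimum(grid + 1.0, b) - grid
        vals = np.asarray(rate_fn(grid + 0.5 * dur), dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError("rate function must be finite on the interval")
        if np.any(vals < 0):
            raise ValueError("rate function must be non-negative")
        lam = vals * dur / 1000.0
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=float)
    starts = np.repeat(lo, counts)
    widths = np.repeat(dur, counts)
    times = np.sort(starts + widths * rng.random(total))
    # strict ordering for storage: perturb exact ties by float spacing
    dup = np.flatnonzero(np.diff(times) == 0)
    while dup.size:
        times[dup + 1] = np.nextafter(times[dup + 1], np.inf)
        times = np.sort(times)
        dup = np.flatnonzero(np.diff(times) == 0)
    return times


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """One draw from a truncated normal via inverse-CDF (fast, seedable)."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + rng.random() * (b - a)
    # clip away exact 0/1 to keep ndtri finite for extreme bounds
    u = min(max(u, 1e-12), 1.0 - 1e-12)
    return float(np.clip(mean + sd * ndtri(u), lo, hi))


def _dist_field(mean: float, sd: float, lo: float = -np.inf,
                hi: float = np.inf) -> Tuple[float, float, float, float]:
    return (mean, sd, lo, hi)


@dataclass
class ParamDistributions:
    """Across-unit distributions of rate-profile parameters.

    Each entry is (mean, sd, lower, upper); units are drawn from normals
    truncated at the validity bounds.  Zero sd pins the parameter (an
    "injected" onset).  Onset latencies default to pinned values so the
    population latency analyses have a defined ground truth; rate and gain
    parameters vary across units, which the neuron-level bootstrap requires.
    """

    baseline_rate: tuple = _dist_field(10.0, 2.0, 0.5, np.inf)
    visual_response_rate: tuple = _dist_field(25.0, 5.0, 2.0, np.inf)
    visual_latency: tuple = _dist_field(70.0, 10.0, 40.0, 120.0)
    cue_transient_gain: tuple = _dist_field(1.3, 0.1, 1.0, 2.0)
    nce_onset_latency: tuple = _dist_field(90.0, 0.0, 0.0, 400.0)
    distractor_suppression: tuple = _dist_field(0.3, 0.08, 0.0, 0.9)
    distractor_enhancement: tuple = _dist_field(0.3, 0.08, 0.0, 0.9)
    u_early: tuple = _dist_field(3.0, 1.0, 0.5, np.inf)
    u_mid: tuple = _dist_field(-3.0, 1.0, -np.inf, -0.5)
    u_late: tuple = _dist_field(11.0, 2.0, 0.5, np.inf)
    resolution_latency: tuple = _dist_field(600.0, 0.0, 0.0, 1500.0)
    selection_amplitude: tuple = _dist_field(8.0, 2.0, 1.0, np.inf)
    selection_ramp_ms: tuple = _dist_field(300.0, 0.0, 10.0, np.inf)
    dim_transient_rate: tuple = _dist_field(15.0, 4.0, 0.0, np.inf)
    noise_cv: tuple = _dist_field(0.2, 0.0, 0.0, 2.0)

    def _draw(self, dist, rng: np.random.Generator) -> float:
        mean, sd, lo, hi = dist
        if sd == 0:
            return float(np.clip(mean, lo, hi))
        return _truncated_normal(rng, mean, sd, lo, hi)

    def draw(self, rng: np.random.Generator) -> RateProfileParams:
        p = RateProfileParams(
            baseline_rate=self._draw(self.baseline_rate, rng),
            visual_response_rate=self._draw(self.visual_response_rate, rng),
            visual_latency=self._draw(self.visual_latency, rng),
            cue_transient_gain=self._draw(self.cue_transient_gain, rng),
            nce_onset_latency=self._draw(self.nce_onset_latency, rng),
            distractor_suppression=self._draw(self.distractor_suppression, rng),
            distractor_enhancement=self._draw(self.distractor_enhancement, rng),
            target_u_shape=(self._draw(self.u_early, rng),
                            self._draw(self.u_mid, rng),
                            self._draw(self.u_late, rng)),
            resolution_latency=self._draw(self.resolution_latency, rng),
            selection_amplitude=self._draw(self.selection_amplitude, rng),
            selection_ramp_ms=self._draw(self.selection_ramp_ms, rng),
            dim_transient_rate=self._draw(self.dim_transient_rate, rng),
            noise_cv=self._draw(self.noise_cv, rng),
        )
        p.validate()
        return p


@dataclass
class SynthConfig:
    """Configuration of one synthetic session (and its behavior).

    Defaults reflect the study conditions: 8 task cells (2 rules x 2
    congruencies x 2 target sides) with 35 correct-trial targets per cell
    (the sessions contained 32-40), distractor dimming in 50% of trials,
    session accuracies near 94% (congruent) vs 81% (incongruent) and hit
    RTs near 365 vs 377 ms.
    """

    session_id: str = "synth-000"
    subject_id: str = "S"
    subjects: tuple = ("S", "R")
    n_units: int = 120
    trials_per_condition: int = 35
    distractor_dim_prob: float = 0.5
    fixation_break_prob: float = 0.05
    accuracy_congruent: float = 0.94
    accuracy_incongruent: float = 0.81
    rt_mean_congruent: float = 365.0
    rt_mean_incongruent: float = 377.0
    rt_sd: float = 40.0
    p_visual: float = 1.0
    p_contra: float = 1.0
    rate_params: ParamDistributions = field(default_factory=ParamDistributions)

    def validate(self) -> None:
        if self.subject_id not in self.subjects:
            raise ValueError("subject_id must be one of subjects")
        for name in ("n_units", "trials_per_condition"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
        for name in ("distractor_dim_prob", "fixation_break_prob",
                     "accuracy_congruent", "accuracy_incongruent",
                     "p_visual", "p_contra"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be >= 0")
        for name in ("rt_mean_congruent", "rt_mean_incongruent"):
            if not (RESPONSE_WINDOW[0] <= getattr(self, name) <= RESPONSE_WINDOW[1]):
                raise ValueError(f"{name} must lie in the response window "
                                 f"{RESPONSE_WINDOW}")


def _draw_timeline(rng: np.random.Generator, dim_prob: float) -> TaskTimeline:
    """Event times on a 1 ms grid, satisfying the task constraints."""
    td = float(rng.integers(int(TARGET_DIM_RANGE[0]), int(TARGET_DIM_RANGE[1]) + 1))
    dd = None
    if rng.random() < dim_prob:
        hi = min(DISTRACTOR_DIM_RANGE[1], td - MIN_DIM_SEPARATION)
        dd = float(rng.integers(int(DISTRACTOR_DIM_RANGE[0]), int(hi) + 1))
    return TaskTimeline(distractor_dim_onset=dd, target_dim_onset=td,
                        trial_end=td + 700.0)


def _draw_rt(rng: np.random.Generator, mean: float, sd: float) -> float:
    lo, hi = RESPONSE_WINDOW
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    return _truncated_normal(rng, mean, sd, lo, hi)


def _draw_outcome(rng: np.random.Generator, cfg: SynthConfig,
                  congruency: str) -> str:
    if rng.random() < cfg.fixation_break_prob:
        return "fixation_break"
    acc = cfg.accuracy_congruent if congruency == "congruent" \
        else cfg.accuracy_incongruent
    if rng.random() < acc:
        return "hit"
    return "false_alarm" if rng.random() < 0.5 else "miss"


def _draw_trials(cfg: SynthConfig, rng: np.random.Generator) -> List[Trial]:
    cells = [(rule, congr, side) for rule in RULES for congr in CONGRUENCIES
             for side in SIDES]
    conds = [cell for cell in cells for _ in range(cfg.trials_per_condition)]
    order = rng.permutation(len(conds))
    trials: List[Trial] = []
    for idx in order:
        rule, congr, side = conds[idx]
        tl = _draw_timeline(rng, cfg.distractor_dim_prob)
        outcome = _draw_outcome(rng, cfg, congr)
        cond = condition_cell(rule, congr, side, outcome=outcome)
        if outcome == "hit":
            mean = cfg.rt_mean_congruent if congr == "congruent" \
                else cfg.rt_mean_incongruent
            rt = _draw_rt(rng, mean, cfg.rt_sd)
            tl = dataclasses.replace(tl, response_time=tl.target_dim_onset + rt)
        trials.append(Trial(timeline=tl, condition=cond))
    return trials


def _unit_kind(rng: np.random.Generator, cfg: SynthConfig) -> str:
    if rng.random() >= cfg.p_visual:
        return "nonvisual"
    return "visual_contra" if rng.random() < cfg.p_contra else "visual_ipsi"


def _params_for_kind(params: RateProfileParams, kind: str) -> RateProfileParams:
    if kind == "visual_contra":
        return params
    if kind == "nonvisual":
        return dataclasses.replace(
            params, visual_response_rate=params.baseline_rate,
            cue_transient_gain=1.0, distractor_suppression=0.0,
            distractor_enhancement=0.0, target_u_shape=(0.0, 0.0, 0.0),
            selection_amplitude=0.0, dim_transient_rate=0.0)
    if kind == "visual_ipsi":
        # visually driven, but the RF covers the ipsilateral stimulus: no
        # congruency modulation and the dimming response follows out-RF dims
        return dataclasses.replace(
            params, cue_transient_gain=1.0, distractor_suppression=0.0,
            distractor_enhancement=0.0, target_u_shape=(0.0, 0.0, 0.0),
            selection_amplitude=0.0)
    raise ValueError(f"unknown unit kind {kind!r}")


def _mirror_condition(cond: TrialCondition) -> TrialCondition:
    """Swap hemifields, for units whose RF covers the ipsilateral stimulus."""
    flip = {"in_rf": "out_rf", "out_rf": "in_rf"}
    return dataclasses.replace(cond, target_side=flip[cond.target_side],
                               cue_side=flip[cond.cue_side])


def generate_session(config: SynthConfig, seed: int) -> SessionData:
    """Generate a complete synthetic session. Same seed, same output."""
    config.validate()
    rng = np.random.default_rng(seed)
    trials = _draw_trials(config, rng)
    units: List[UnitSpikes] = []
    kinds: List[str] = []
    for ui in range(config.n_units):
        kind = _unit_kind(rng, config)
        kinds.append(kind)
        params = _params_for_kind(config.rate_params.draw(rng), kind)
        spikes: List[np.ndarray] = []
        for tr in trials:
            cond = tr.condition
            if kind == "visual_ipsi":
                cond = _mirror_condition(cond)
            prof = rate_profile(params, cond, tr.timeline)
            if params.noise_cv > 0:
                shape = 1.0 / params.noise_cv ** 2
                gain = rng.gamma(shape, 1.0 / shape)
                prof = prof.scaled(gain)
            spikes.append(sample_spikes(
                prof, (tr.timeline.fixation_onset, tr.timeline.trial_end), rng))
        units.append(UnitSpikes(
            unit_id=f"{config.session_id}-u{ui:03d}", channel=ui % 16,
            spikes=spikes))
        units[-1].validate(trials)
    session = SessionData(
        session_id=config.session_id, subject_id=config.subject_id,
        trials=trials, units=units, subjects=config.subjects,
        meta={"generator": "ncelab.synth", "seed": int(seed),
              "unit_kinds": {u.unit_id: k for u, k in zip(units, kinds)}})
    session.validate()
    return session


def generate_sessions(config: SynthConfig, seed: int,
                      n_sessions: int) -> List[SessionData]:
    """Generate ``n_sessions`` independent sessions for one subject.

    Sessions get distinct ids and child seeds spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sessions)
    out = []
    for i, child in enumerate(children):
        cfg = dataclasses.replace(
            config, session_id=f"{config.session_id}-s{i:02d}")
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(generate_session(cfg, child_seed))
    return out


def generate_behavior(config: SynthConfig, seed: int,
                      n_sessions: int = 12) -> pd.DataFrame:
    """Behavior-only simulation: per-session, per-congruency counts and RTs.

    Draws trial outcomes and hit RTs for ``n_sessions`` sessions without
    simulating spikes.  Returns one row per (session, congruency) with hit /
    false-alarm / miss counts, accuracy and mean RT (ms after target
    dimming, constrained to the 200-700 ms response window).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    n_per_congr = 4 * config.trials_per_condition  # 4 cells per congruency
    for s in range(n_sessions):
        for congr in CONGRUENCIES:
            counts = {"hit": 0, "false_alarm": 0, "miss": 0, "fixation_break": 0}
            rts = []
            mean_rt = config.rt_mean_congruent if congr == "congruent" \
                else config.rt_mean_incongruent
            for _ in range(n_per_congr):
                outcome = _draw_outcome(rng, config, congr)
                counts[outcome] += 1
                if outcome == "hit":
                    rts.append(_draw_rt(rng, mean_rt, config.rt_sd))
            n_scored = counts["hit"] + counts["false_alarm"] + counts["miss"]
            rows.append({
                "session": f"{config.session_id}-b{s:02d}",
                "subject_id": config.subject_id,
                "congruency": congr,
                "n_hit": counts["hit"],
                "n_false_alarm": counts["false_alarm"],
                "n_miss": counts["miss"],
                "n_fixation_break": counts["fixation_break"],
                "accuracy": counts["hit"] / n_scored if n_scored else np.nan,
                "mean_rt": float(np.mean(rts)) if rts else np.nan,
            })
    return pd.DataFrame(rows)
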