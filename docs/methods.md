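# Methods

This note documents the models, estimators and numerical choices behind
`ncelab`, and what the synthetic-data generator does and does not emulate.

## Task model

All times are milliseconds referenced to color-cue onset (t = 0).  Fixed
events: fixation onset −1600, rule cue −1100 to −600, peripheral stimuli
onset −600, color cue 0–200.  Jittered events are drawn uniformly on a
1 ms grid: target dimming in [860, 2150] (i.e. 660–1950 after cue
offset); distractor dimming, present in 50% of trials, in [400, 1700] and
at least 300 ms before target dimming; the trial ends 700 ms after target
dimming.  A hit is a button press 200–700 ms after target dimming.

Condition labels are derived, not stored independently: congruency is a
pure function of (cue color, cue side) — red-left / pink-right is
congruent — and target side follows from the rule.  The recorded
hemisphere is the right one, so `in_rf` denotes the left hemifield.  One
consequence used throughout: the cue falls inside the RF in every cell
except the incongruent color-rule trials of target-role conditions, and
*only* in the incongruent color-rule trials of distractor-role conditions.
This asymmetry is why detection latencies are estimated per rule, and why
the spatial rule provides the stimulus-clean estimate.

## Generative model of unit activity

Each unit's firing rate is piecewise constant over a trial:

1. baseline rate until `stimuli_onset + visual_latency`, then a sustained
   visual-response rate (defaults 10 and 25 sp/s, visual latency 70 ms);
2. a multiplicative cue transient (gain 1.3) 60–200 ms after cue onset
   when the cue is inside the RF;
3. from the congruency-onset latency (default 90 ms):
   distractor-role trials are scaled by (1 − suppression) when congruent
   and (1 + enhancement) when incongruent (defaults 0.3/0.3 — a
   persistent ±7.5 sp/s congruency effect around 25 sp/s);
   target-role trials are scaled by (1 + enhancement) in both congruency
   levels, and congruent trials additionally receive the signed
   three-window amplitude profile (+3, −3, +11 sp/s over [0,200],
   [300,750], [750,1600] ms) that produces the U-shaped target-role NCE;
4. in incongruent target-role trials a selection ramp (default 8 sp/s
   reached over 300 ms, staircased at 10 ms) starts at the resolution
   latency (default 600 ms).  Placing the ramp on the target-role
   response, rather than suppressing the distractor-role response, keeps
   the incongruent TarIn−DisIn contrast exactly zero before the ramp and
   equal to the ramp after it, keeps the distractor-role NCE flat
   (persistent), and lets the target-role NCE share the overall selection
   signal's time course — which is what makes the selection-vs-NCE
   correlation much higher for target-role than distractor-role
   conditions.  The late window amplitude (+11) exceeds the ramp so the
   late target-role NCE stays positive;
5. a +15 sp/s transient 50–200 ms after the dimming of the in-RF stimulus
   (target dimming for TarIn trials, distractor dimming for DisIn
   trials).  The distractor-dimming transient falls entirely inside the
   0–200 ms exclusion mask, which is exactly why that mask exists;
6. a per-trial multiplicative gain with CV 0.2 (gamma distributed,
   mean 1) modeling slow excitability fluctuations.

Across units, every rate/gain parameter is drawn from a truncated normal
(the neuron-level bootstrap needs across-unit variance); the onset
latencies default to pinned values so population latency analyses have a
defined ground truth.  A configurable fraction of units is non-visual
(flat baseline) or has an ipsilateral RF (visual but unmodulated, dimming
response mirrored), giving the selection stage something to reject.

Spike trains are sampled exactly: within each constant-rate segment the
count is Poisson(rate × duration) and times are uniform — statistically
identical to 1 ms thinning of the same profile (which remains the
fallback for arbitrary callable rates) but exact and much faster.  Ties
are broken by nudging one float ULP so stored timestamps are strictly
increasing.

What the generator does **not** emulate: burstiness/refractoriness
(counts are Poisson conditional on the gain), spike-count correlations
between units, eye-position artifacts, non-stationarity across a session,
and any structure in error trials (rates do not depend on outcome).
Passing tests therefore demonstrate correctness of the estimators under
the assumed statistical structure, not robustness to every property of
real recordings.

Behavior is generated per trial: hit probability 0.94 (congruent) vs 0.81
(incongruent); errors split evenly between false alarms and misses; 5%
fixation breaks (excluded from accuracy by definition); hit RTs from a
normal truncated to the 200–700 ms response window with means 365/377 ms
and SD 40 ms.

## Estimators

**Masked PSTH.**  Rates live on half-open 10 ms bins over [−1700, 1600] ms
(spikes at an edge belong to the right bin).  Per unit and condition,
`rate(bin) = Σ_trials spikes in (bin ∩ valid) / Σ_trials valid time`,
where valid time excludes [distractor dim, +200 ms) and everything from
target-dimming onset; partial overlaps down-weight a bin via its valid
time rather than dropping it.  Bins with zero valid time are NaN
(missing), never zero.  Smoothing is a centered moving mean including all
bins whose centers lie within ±width/2 (width 100 → 11 bins, width 50 →
5 bins); edge bins average their available partial window, avoiding edge
attenuation.

**Unit selection.**  Stage 1: per-trial mean rates in [−600, −100)
(post-stimuli) vs [−1400, −1100) (post-fixation baseline), two-tailed
paired t-test over hit trials, pass iff p < 0.05 *and* the stimulus
window is higher.  Stage 2: rates 50–200 ms after target dimming, in-RF
vs out-RF target trials.  These are disjoint trial sets, so the default
test is Welch's two-sample t-test; a `paired` option pairs trials by task
order for a literal paired-test reading.  α = 0.05, no multiple-testing
correction across units.  Units with fewer than two usable trials per
group, or degenerate variances (e.g. zero spikes), are flagged
untestable and excluded.

**Contrasts and stars.**  Per unit, the NCE and target-selection series
are differences of raw 10 ms condition PSTHs on the shared grid.  Star
tracks test window means of the raw bins (50 ms windows for the NCE,
100 ms for target selection, both stepped 10 ms) with a two-tailed
Wilcoxon signed-rank across units at α = 0.05.

**Signed-rank test.**  Zero differences are dropped.  Samples of ≤ 50
tie-free values use SciPy's exact distribution; ties or larger samples
use a normal approximation with continuity correction whose variance is
`Σ r_i² / 4` over the midranks — an identity (under H₀ the statistic is
`Σ r_i B_i` with iid Bernoulli(1/2) signs) that equals the classical
tie-corrected formula exactly and vectorizes across time bins.  On
congruency-null simulations the attained starred-bin fraction is ≈ 0.0475
(slightly conservative, as expected of an exact/discrete test at n = 40).

**Modulation indices.**  Computed from raw spike counts over the stated
windows, not from smoothed PSTHs (the windows are long relative to the
bins; smoothing would leak mass across window boundaries).  Baseline
variant: R = mean rate 100–300 ms post cue, R_b = mean rate over the
200 ms before the cue; MI = (R − R_b)/(R + R_b); per-unit significance is
a signed-rank test of the per-trial R − R_b differences (the only paired
structure available at unit level).  Congruency variant:
(R_con − R_incon)/(R_con + R_incon) over [0,200], [500,700] or
[1000,1200] ms of target-role hit trials, with the exclusion mask applied
(the late window can overlap distractor dimming or truncation); per-unit
p is a two-sample rank test since the two trial sets are unpaired.
Units with A + B = 0 are excluded and logged.  |MI| ≤ 1 always, with
equality iff one rate is zero.

**Latencies.**  Detection: two-tailed signed-rank per raw 10 ms bin over
−100…1600 ms; the latency is the left edge of the first run of ≥ 5
consecutive significant bins (edge vs center being otherwise
underdetermined, *left edge* is used; a sign-consistency flag is available but off by
default, matching the literal "significant NCE" reading).  Resolution:
the per-unit incongruent-trial selection series is smoothed (100 ms
moving mean, 10 ms step) before testing over 400–1600 ms, and a
qualifying bin must also have a positive population median (the signal
must indicate target > distractor).  Because the cue itself can drive
activity for up to ~410 ms (200 ms cue + visual latency + recovery), the
earliest reportable resolution latency is 410 ms: earlier runs are
reported as 410 flagged *left-censored at window start*.

**Bootstrap.**  Resample the units with replacement, recompute the
latency per replicate (10,000 replicates by default; the smoothing is
linear per unit, so the resolution matrix is presmoothed once).  The RNG
is a master seed spawning one child stream per replicate.  Replicates
without a qualifying run are censored; median and IQR summarize the
non-censored replicates, and the median is reported censored when more
than half the replicates are.  Replicate tests use the vectorized normal
approximation throughout (tens of thousands of column tests per call);
point estimates use the exact small-sample path where applicable.
Whiskers for plotting follow the 1.5 × IQR rule (outliers never affect
the median or IQR).

A property of the resolution estimator worth knowing: centered smoothing
correlates neighboring bins over ±50 ms, so the effective number of
independent tests in the 120-bin window is ~12, and a single spurious
fluctuation can satisfy the run-of-5 rule.  On default-strength
simulations roughly one cohort in six shows a false early run; the
recovery checks therefore use a strong-amplitude ramp (12 sp/s over
200 ms) and summarize the median over five cohorts.  Detection, which
tests raw bins, does not share this failure mode.

**Regression.**  Ordinary least squares of the population-mean overall
selection signal on the population-mean NCE over the raw 10 ms bins in
[200, 1200) ms (100 bins).  Adjacent bins of a population mean are
serially correlated, so the slope's nominal p-value is optimistic; the
result carries a `serial_correlation_caveat` flag and p-values are meant
descriptively.  The two correlations share the selection series, so the
default comparison resamples units, rebuilds all three population series
and reports the two-tailed bootstrap tail probability of r₁ − r₂ (with a
resolution floor of 1/(n_boot + 1)); a Fisher-z comparison treating the
correlations as independent is available as a labelled approximation.

**Behavior.**  Session accuracy = hits/(hits + false alarms + misses)
per congruency (fixation breaks excluded by construction); RT =
response time − target-dimming onset, summarized per session by the mean
over all hit trials (median available; distractor-dimming hits are
included).  Congruency effects are two-tailed paired t-tests across
sessions per subject, requiring ≥ 2 sessions with both congruency levels.

## Data container

One HDF5 file per session: `/trials` holds columnar float64 event times
(NaN = absent) and fixed-width label strings; `/units/<id>` holds the
concatenated spike timestamps plus an offsets index (ragged per-trial
lists), selection results as JSON attributes; the root carries a schema
version string (unknown versions are rejected loudly), subject roster and
free-form metadata.  All times are float64 ms referenced to cue onset, so
write→read round trips are bit exact and verified by checksum-style tests.
The deposit adapter ingests a directory of such containers and raises an
"unsupported deposit layout" error with a file inventory for anything
else; mapping an external deposit's native layout requires finalizing
against that deposit itself.

## Pipeline

`run_pipeline` executes simulate/ingest → select → psth → congruency →
latency → regression → behavior from a single YAML mapping with the
standard analysis as the zero-config default; every windows/α/width knob
is config-surfaced.  Outputs are CSV (deterministic formatting; reruns
with the same config and seed are byte-identical), plus a JSON manifest
with config hash, seed, stage timings and file list.  Per-subject
contrast matrices are cached as `.npz` under `out/cache`, so a stage
subset (e.g. `latency` alone) reproduces the full run's outputs from
cache.  A user-supplied `subjects` roster replaces the default roster
outright rather than merging into it.

## Default problem sizes

Analysis-grade simulated cohorts use 120 units × 35 trials per condition
(within the 32–40 per-condition range of the recorded sessions); the
type-I calibration uses 100 null cohorts of 40 units × 16 trials;
recovery checks use 1,000 bootstrap replicates (the full analysis
default is 10,000).  These sizes were chosen so each property is measured
with comfortable statistical margin by a desk-scale run.

## Known limitations

- The resolution-latency estimator's false-early-run behavior (above) is
  a property of the published criterion, not of this implementation;
  interpret single-cohort resolution latencies with the bootstrap IQR.
- The congruency-MI per-unit p-value uses an unpaired rank test because
  no within-unit pairing exists across congruency levels; it is not
  comparable to the paired baseline-MI p-value.
- `import_zenodo` understands only this package's container layout.
- Error-trial activity is not modeled; analyses restrict to hits by
  design, so this costs nothing for the implemented statistics.
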