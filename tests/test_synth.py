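"""Generator contracts: determinism, rate arithmetic, Poisson oracles."""

import dataclasses

import numpy as np
import pytest

from conftest import null_rate_params
from ncelab.synth import (PiecewiseRate, RateProfileParams, SynthConfig,
                          generate_behavior, generate_session, rate_profile,
                          sample_spikes)
from ncelab.task import TaskTimeline, condition_cell


def _timeline(dd=None, td=1500.0):
    return TaskTimeline(distractor_dim_onset=dd, target_dim_onset=td,
                        trial_end=td + 700.0)


class TestConfigValidation:
    def test_negative_counts_rejected_naming_field(self):
        with pytest.raises(ValueError, match="n_units"):
            SynthConfig(n_units=-1).validate()

    def test_probability_bounds_rejected_naming_field(self):
        with pytest.raises(ValueError, match="accuracy_incongruent"):
            SynthConfig(accuracy_incongruent=1.5).validate()
        with pytest.raises(ValueError, match="distractor_dim_prob"):
            SynthConfig(distractor_dim_prob=-0.1).validate()

    def test_rate_param_bounds(self):
        with pytest.raises(ValueError, match="distractor_suppression"):
            RateProfileParams(distractor_suppression=1.0).validate()
        with pytest.raises(ValueError, match="baseline_rate"):
            RateProfileParams(baseline_rate=-1.0).validate()


class TestGenerateSession:
    def test_balanced_condition_counts(self):
        session = generate_session(SynthConfig(n_units=0,
                                               trials_per_condition=35), 0)
        assert session.n_trials == 8 * 35
        tab = session.condition_table()
        counts = tab.groupby(["rule", "congruency", "target_side"]).size()
        assert (counts == 35).all()

    def test_seeded_determinism_is_exact(self):
        cfg = SynthConfig(n_units=3, trials_per_condition=4)
        a = generate_session(cfg, 42)
        b = generate_session(cfg, 42)
        for ua, ub in zip(a.units, b.units):
            for sa, sb in zip(ua.spikes, ub.spikes):
                assert sa.tobytes() == sb.tobytes()
        assert a.condition_table().equals(b.condition_table())

    def test_distractor_dim_fraction_binomial(self):
        n = 10_000
        cfg = SynthConfig(n_units=0, trials_per_condition=n // 8,
                          distractor_dim_prob=0.5)
        session = generate_session(cfg, 1)
        frac = np.mean([t.timeline.distractor_dim_onset is not None
                        for t in session.trials])
        sd = np.sqrt(0.5 * 0.5 / session.n_trials)
        assert abs(frac - 0.5) < 3 * sd


class TestRateProfile:
    def test_zero_modulations_are_congruency_invariant(self):
        p = RateProfileParams(cue_transient_gain=1.0,
                              distractor_suppression=0.0,
                              distractor_enhancement=0.0,
                              target_u_shape=(0.0, 0.0, 0.0),
                              selection_amplitude=0.0)
        tl = _timeline()
        grid = np.arange(-1600.0, tl.target_dim_onset, 1.0)
        for rule in ("spatial", "color"):
            for side in ("in_rf", "out_rf"):
                con = rate_profile(p, condition_cell(rule, "congruent", side), tl)
                inc = rate_profile(p, condition_cell(rule, "incongruent", side), tl)
                assert np.array_equal(con(grid), inc(grid))

    def test_distractor_suppression_enhancement_arithmetic(self):
        # post-cue sustained 20 sp/s, 30% suppression/enhancement -> 14 / 26
        p = RateProfileParams(visual_response_rate=20.0,
                              cue_transient_gain=1.0,
                              distractor_suppression=0.3,
                              distractor_enhancement=0.3,
                              dim_transient_rate=0.0)
        tl = _timeline()
        con = rate_profile(p, condition_cell("spatial", "congruent", "out_rf"), tl)
        inc = rate_profile(p, condition_cell("spatial", "incongruent", "out_rf"), tl)
        t = np.array([200.0, 500.0, 1000.0])
        assert np.allclose(con(t), 14.0)
        assert np.allclose(inc(t), 26.0)
        # identical before the congruency-onset latency (cue gain disabled)
        pre = np.array([-300.0, 0.0, 80.0])
        assert np.array_equal(con(pre), inc(pre))

    def test_integral_matches_mean_spike_count(self):
        p = RateProfileParams()
        tl = _timeline(dd=700.0)
        cond = condition_cell("color", "incongruent", "out_rf")
        prof = rate_profile(p, cond, tl)
        expected = prof.integral(tl.fixation_onset, tl.trial_end)
        rng = np.random.default_rng(9)
        n_rep = 5000
        counts = [sample_spikes(prof, (tl.fixation_onset, tl.trial_end),
                                rng).size for _ in range(n_rep)]
        se = np.sqrt(expected / n_rep)  # Poisson: var = mean
        assert abs(np.mean(counts) - expected) < 3 * se


class TestSampleSpikes:
    def test_zero_rate_gives_no_spikes(self):
        prof = PiecewiseRate(np.array([0.0, 1000.0]), np.array([0.0]))
        assert sample_spikes(prof, (0.0, 1000.0), 0).size == 0

    def test_constant_rate_poisson_mean(self):
        prof = PiecewiseRate(np.array([0.0, 2000.0]), np.array([50.0]))
        rng = np.random.default_rng(2)
        counts = [sample_spikes(prof, (0.0, 2000.0), rng).size
                  for _ in range(2000)]
        se = np.sqrt(100.0 / 2000)
        assert abs(np.mean(counts) - 100.0) < 3 * se

    def test_spikes_sorted_and_inside_range(self):
        prof = PiecewiseRate(np.array([0.0, 500.0, 1000.0]),
                             np.array([80.0, 20.0]))
        st = sample_spikes(prof, (100.0, 900.0), 5)
        assert np.all(np.diff(st) > 0)
        assert st[0] >= 100.0 and st[-1] < 900.0

    def test_step_profile_recovered_within_one_bin(self):
        prof = PiecewiseRate(np.array([0.0, 500.0, 1000.0]),
                             np.array([5.0, 60.0]))
        rng = np.random.default_rng(3)
        edges = np.arange(0.0, 1001.0, 10.0)
        counts = np.zeros(edges.size - 1)
        n_rep = 2000
        for _ in range(n_rep):
            counts += np.histogram(sample_spikes(prof, (0.0, 1000.0), rng),
                                   bins=edges)[0]
        rate = 1000.0 * counts / (10.0 * n_rep)
        mid = (rate > 32.5).astype(int)  # halfway threshold
        jump = int(np.flatnonzero(np.diff(mid))[0] + 1)
        assert abs(edges[jump] - 500.0) <= 10.0

    def test_negative_callable_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sample_spikes(lambda t: np.full_like(t, -1.0), (0.0, 100.0), 0)

    def test_nonfinite_callable_rate_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sample_spikes(lambda t: np.full_like(t, np.inf), (0.0, 100.0), 0)


class TestBehaviorGeneration:
    def test_perfect_accuracy_gives_zero_errors(self):
        cfg = SynthConfig(accuracy_congruent=1.0, accuracy_incongruent=1.0,
                          fixation_break_prob=0.0)
        tab = generate_behavior(cfg, 0, n_sessions=3)
        assert (tab["n_false_alarm"] == 0).all()
        assert (tab["n_miss"] == 0).all()
        assert (tab["accuracy"] == 1.0).all()

    def test_rts_respect_response_window(self):
        tab = generate_behavior(SynthConfig(), 1, n_sessions=5)
        assert tab["mean_rt"].between(200.0, 700.0).all()

    def test_configured_accuracies_recovered(self):
        cfg = SynthConfig(trials_per_condition=40, fixation_break_prob=0.0)
        tab = generate_behavior(cfg, 2, n_sessions=20)
        for congr, target in (("congruent", 0.94), ("incongruent", 0.81)):
            accs = tab.loc[tab["congruency"] == congr, "accuracy"]
            n = 4 * 40 * 20
            sd = np.sqrt(target * (1 - target) / n)
            assert abs(accs.mean() - target) < 3 * sd


def test_pre_cue_rates_are_congruency_invariant(small_session):
    """Simulated pre-cue [-600, 0] ms rates do not differ by congruency."""
    per_congr = {"congruent": [], "incongruent": []}
    for u in small_session.units:
        for tr, st in zip(small_session.trials, u.spikes):
            n = np.count_nonzero((st >= -600.0) & (st < 0.0))
            per_congr[tr.condition.congruency].append(n / 0.6)
    a = np.asarray(per_congr["congruent"])
    b = np.asarray(per_congr["incongruent"])
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    assert abs(a.mean() - b.mean()) < 3 * se
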