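"""NCE / target-selection contrasts and modulation indices."""

import numpy as np
import pytest

from ncelab.congruency import (mi_baseline, mi_congruency, mi_population,
                               nce_series, target_selection_series)
from ncelab.congruency import _difference_series
from ncelab.datamodel import UnitSpikes
from ncelab.psth import cell
from ncelab.task import TaskTimeline, Trial, condition_cell


def _trial(rule, congruency, target_side, td=1500.0, dd=None):
    tl = TaskTimeline(distractor_dim_onset=dd, target_dim_onset=td,
                      trial_end=td + 700.0)
    return Trial(timeline=tl,
                 condition=condition_cell(rule, congruency, target_side))


def _uniform_spikes(rate, a, b, rng):
    n = rng.poisson(rate * (b - a) / 1000.0)
    return np.sort(rng.uniform(a, b, n))


class TestNCESeries:
    def test_single_unit_single_trial_is_psth_difference(self):
        trials = [_trial("spatial", "congruent", "in_rf"),
                  _trial("spatial", "incongruent", "in_rf")]
        unit = UnitSpikes("u", 0, [np.array([5.0, 15.0]), np.array([5.0])])
        ser = nce_series([unit], trials, role="target", rule="spatial",
                         width=0.0)
        c = ser.bin_centers
        assert ser.unit_raw[0, c == 5.0] == pytest.approx(0.0)    # 100 - 100
        assert ser.unit_raw[0, c == 15.0] == pytest.approx(100.0)  # 100 - 0

    def test_empty_cell_raises_naming_cell(self, small_session):
        spatial_only = [t for t in small_session.trials
                        if t.condition.rule == "spatial"]
        units = [UnitSpikes(u.unit_id, u.channel,
                            [s for s, t in zip(u.spikes, small_session.trials)
                             if t.condition.rule == "spatial"])
                 for u in small_session.units[:2]]
        with pytest.raises(ValueError, match="color"):
            nce_series(units, spatial_only, role="target", rule="color")

    def test_antisymmetry_under_label_swap(self, small_session):
        a = _difference_series(
            small_session.units, small_session.trials,
            cell(congruency="congruent", target_side="out_rf"),
            cell(congruency="incongruent", target_side="out_rf"),
            name="fwd", width=50.0, star_width=50.0,
            t_range=(-1700.0, 1600.0), alpha=0.05)
        b = _difference_series(
            small_session.units, small_session.trials,
            cell(congruency="incongruent", target_side="out_rf"),
            cell(congruency="congruent", target_side="out_rf"),
            name="rev", width=50.0, star_width=50.0,
            t_range=(-1700.0, 1600.0), alpha=0.05)
        assert np.array_equal(a.unit_raw, -b.unit_raw, equal_nan=True)
        assert np.array_equal(a.p, b.p)  # two-tailed: sign invariant

    def test_distractor_nce_negative_and_starred_after_onset(self,
                                                             small_session):
        ser = nce_series(small_session.units, small_session.trials,
                         role="distractor", rule="spatial", width=0.0)
        c = ser.bin_centers
        post = (c > 150.0) & (c < 800.0)
        assert np.nanmean(ser.pop_mean[post]) < -5.0
        assert (ser.p[post] < 0.05).mean() > 0.9
        pre = (c > -500.0) & (c < 0.0)
        assert (ser.p[pre] < 0.05).mean() < 0.3


class TestTargetSelection:
    def test_equal_conditions_give_exact_zero(self):
        trials = [_trial("spatial", "incongruent", "in_rf"),
                  _trial("spatial", "incongruent", "out_rf")]
        unit = UnitSpikes("u", 0, [np.array([5.0]), np.array([5.0])])
        ser = target_selection_series([unit], trials,
                                      congruency="incongruent", width=0.0)
        finite = np.isfinite(ser.unit_raw[0])
        assert np.allclose(ser.unit_raw[0, finite], 0.0)

    def test_selection_rises_after_resolution_latency(self, small_session):
        ser = target_selection_series(small_session.units,
                                      small_session.trials,
                                      congruency="incongruent", width=0.0)
        c = ser.bin_centers
        late = (c > 1000.0) & (c < 1500.0)
        early = (c > 250.0) & (c < 500.0)
        assert np.nanmean(ser.pop_mean[late]) > \
            np.nanmean(ser.pop_mean[early]) + 3.0


class TestModulationIndices:
    def _session_with_rates(self, r_post, r_base, rule="spatial",
                            congruency="congruent", side="out_rf"):
        """One deterministic unit: exact counts in the MI windows."""
        trial = _trial(rule, congruency, side)
        spikes = np.concatenate([
            np.linspace(-199.9, -0.1, int(r_base * 0.2)),      # baseline
            np.linspace(100.1, 299.9, int(r_post * 0.2)),      # response
        ])
        unit = UnitSpikes("u", 0, [np.sort(spikes)])
        return unit, [trial]

    def test_equal_rates_give_zero(self):
        unit, trials = self._session_with_rates(20, 20)
        mi = mi_baseline(unit, trials, cell())
        assert mi.value == pytest.approx(0.0)

    def test_baseline_mi_arithmetic(self):
        # R = 30 sp/s, R_b = 10 sp/s -> MI = 0.5
        unit, trials = self._session_with_rates(30, 10)
        mi = mi_baseline(unit, trials, cell())
        assert mi.value == pytest.approx(0.5)

    def test_zero_rates_excluded(self):
        unit, trials = self._session_with_rates(0, 0)
        assert mi_baseline(unit, trials, cell()) is None

    def test_congruency_mi_arithmetic(self):
        # R_con = 30 sp/s, R_incon = 20 sp/s -> MI = 10/50 = 0.2
        tr_c = _trial("spatial", "congruent", "in_rf")
        tr_i = _trial("spatial", "incongruent", "in_rf")
        con = np.linspace(0.1, 199.9, 6)   # 6 spikes / 200 ms
        inc = np.linspace(0.1, 199.9, 4)   # 4 spikes / 200 ms
        unit = UnitSpikes("u", 0, [np.sort(con), np.sort(inc)])
        mi = mi_congruency(unit, [tr_c, tr_i], (0.0, 200.0))
        assert mi.value == pytest.approx(0.2)

    def test_suppressed_congruent_distractor_population(self, small_session):
        """Congruent distractor-role responses are suppressed vs baseline."""
        tab = mi_population(small_session.units, small_session.trials,
                            "baseline",
                            condition=cell(congruency="congruent",
                                           target_side="out_rf"))
        assert tab.attrs["median"] < 0
        assert tab.attrs["population_p"] < 0.05
        tab_inc = mi_population(small_session.units, small_session.trials,
                                "baseline",
                                condition=cell(congruency="incongruent",
                                               target_side="out_rf"))
        assert tab_inc.attrs["median"] > 0

    def test_mi_values_bounded(self, small_session):
        for window in ((0.0, 200.0), (500.0, 700.0), (1000.0, 1200.0)):
            tab = mi_population(small_session.units, small_session.trials,
                                "congruency", window=window)
            assert tab["value"].abs().le(1.0).all()
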