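"""Masked-PSTH arithmetic, exclusion windows and smoothing."""

import dataclasses

import numpy as np
import pytest

from ncelab.datamodel import UnitSpikes
from ncelab.psth import (bin_edges, cell, condition_psth, masked_spike_counts,
                         moving_mean, population_average, trial_validity_mask,
                         valid_time_per_bin)
from ncelab.task import TaskTimeline, Trial, condition_cell


def _trial(dd=None, td=1500.0, **cond_kw):
    tl = TaskTimeline(distractor_dim_onset=dd, target_dim_onset=td,
                      trial_end=td + 700.0)
    cond = condition_cell(cond_kw.pop("rule", "spatial"),
                          cond_kw.pop("congruency", "congruent"),
                          cond_kw.pop("target_side", "in_rf"))
    return Trial(timeline=tl, condition=cond)


def _unit(spike_lists):
    return UnitSpikes("u0", 0, [np.asarray(s, dtype=float)
                                for s in spike_lists])


class TestValidityMask:
    def test_no_dimming_masks_only_after_target_dim(self):
        tl = TaskTimeline(target_dim_onset=1000.0, trial_end=1700.0)
        mask = trial_validity_mask(tl, (-1700.0, 1600.0))
        t = np.arange(-1700.0, 1600.0)
        assert not mask[t < -1600.0].any()       # before fixation onset
        assert mask[(t >= -1600.0) & (t < 1000.0)].all()
        assert not mask[t >= 1000.0].any()

    def test_distractor_dim_excludes_200ms(self):
        tl = TaskTimeline(distractor_dim_onset=500.0, target_dim_onset=1500.0,
                          trial_end=2200.0)
        mask = trial_validity_mask(tl, (-1700.0, 1600.0))
        t = np.arange(-1700.0, 1600.0)
        assert not mask[(t >= 500.0) & (t < 700.0)].any()
        assert mask[(t >= 400.0) & (t < 500.0)].all()
        assert mask[(t >= 700.0) & (t < 1500.0)].all()

    def test_partial_bin_overlap_downweighted(self):
        tl = TaskTimeline(distractor_dim_onset=505.0, target_dim_onset=1500.0,
                          trial_end=2200.0)
        vt = valid_time_per_bin(tl, bin_edges((-1700.0, 1600.0)))
        centers = bin_edges((-1700.0, 1600.0))[:-1] + 5.0
        assert vt[centers == 505.0] == 5.0   # bin [500, 510): 5 valid ms
        assert vt[centers == 515.0] == 0.0
        assert vt[centers == 705.0] == 5.0   # bin [700, 710): 5 valid ms

    def test_masked_duration_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            td = float(rng.integers(860, 2151))
            dd = float(rng.integers(400, min(1700, td - 300) + 1)) \
                if rng.random() < 0.5 else None
            tl = TaskTimeline(distractor_dim_onset=dd, target_dim_onset=td,
                              trial_end=td + 700.0)
            t_range = (-1700.0, 1600.0)
            mask = trial_validity_mask(tl, t_range)
            a, b = -1600.0, min(td, 1600.0)
            overlap = 0.0 if dd is None else max(
                0.0, min(dd + 200.0, b) - max(dd, a))
            assert mask.sum() == (b - a) - overlap
            # per-bin valid time agrees with the per-ms mask
            vt = valid_time_per_bin(tl, bin_edges(t_range))
            assert np.array_equal(vt, mask.reshape(-1, 10).sum(axis=1))


class TestConditionPSTH:
    def test_single_spike_single_trial_arithmetic(self):
        trial = _trial()
        unit = _unit([[5.0]])
        p = condition_psth([unit], [trial], {"all": cell()}, width=0.0)
        centers = p.bin_centers
        assert p.raw_rates[0, 0, centers == 5.0] == 100.0  # 1 spike / 10 ms
        others = p.raw_rates[0, 0, (centers != 5.0)
                             & np.isfinite(p.raw_rates[0, 0])]
        assert (others == 0.0).all()

    def test_delta_smoothing_plateau_is_11_bins(self):
        trial = _trial()
        unit = _unit([[5.0]])
        p = condition_psth([unit], [trial], {"all": cell()}, width=100.0)
        centers = p.bin_centers
        plateau = p.rates[0, 0, np.abs(centers - 5.0) <= 50.0]
        assert plateau.size == 11
        assert np.allclose(plateau, 100.0 / 11.0)
        assert np.allclose(
            p.rates[0, 0, np.abs(centers - 5.0) == 60.0], 0.0)

    def test_constant_rate_unit_within_3se(self):
        rng = np.random.default_rng(4)
        rate = 20.0
        trials, spikes = [], []
        for _ in range(200):
            tr = _trial(td=1500.0)
            n = rng.poisson(rate * 3.1)
            spikes.append(np.sort(rng.uniform(-1600.0, 1500.0, n)))
            trials.append(tr)
        p = condition_psth([_unit(spikes)], trials, {"all": cell()}, width=0.0)
        keep = np.isfinite(p.raw_rates[0, 0])
        valid_s = p.valid_time[0, 0, keep] / 1000.0
        se = np.sqrt(rate / valid_s)
        assert (np.abs(p.raw_rates[0, 0, keep] - rate) < 3.5 * se).all()

    def test_mass_conservation_unmasked(self):
        trial = _trial(td=1000.0)
        st = np.sort(np.random.default_rng(1).uniform(-1600.0, 1000.0, 300))
        p = condition_psth([_unit([st])], [trial], {"all": cell()}, width=0.0)
        r, vt = p.raw_rates[0, 0], p.valid_time[0, 0]
        total = np.nansum(r * vt / 1000.0)
        assert abs(total - st.size) < 1e-9

    def test_removing_dimming_reproduces_unmasked_psth(self):
        rng = np.random.default_rng(2)
        st = np.sort(rng.uniform(-1600.0, 1500.0, 250))
        with_dim = _trial(dd=600.0)
        without = Trial(timeline=dataclasses.replace(
            with_dim.timeline, distractor_dim_onset=None),
            condition=with_dim.condition)
        pa = condition_psth([_unit([st])], [with_dim], {"all": cell()},
                            width=0.0)
        pb = condition_psth([_unit([st])], [without], {"all": cell()},
                            width=0.0)
        same = pa.valid_time[0, 0] == pb.valid_time[0, 0]
        assert np.array_equal(pa.raw_rates[0, 0, same],
                              pb.raw_rates[0, 0, same], equal_nan=True)
        assert (pa.valid_time <= pb.valid_time).all()  # masking never adds

    def test_zero_valid_time_is_missing_not_zero(self):
        trial = _trial(td=1000.0)
        p = condition_psth([_unit([[]])], [trial], {"all": cell()}, width=0.0)
        after = p.bin_centers > 1000.0
        assert np.isnan(p.raw_rates[0, 0, after]).all()


class TestPopulationAverage:
    def test_identical_units_have_zero_sem(self):
        trial = _trial()
        st = [10.0, 100.0, 250.0]
        p = condition_psth([_unit([st]), UnitSpikes("u1", 1,
                                                    [np.array(st)])],
                           [trial], {"all": cell()}, width=0.0)
        pop = population_average(p)
        assert np.allclose(pop["sem"].dropna(), 0.0)

    def test_two_unit_mean(self):
        trial = _trial()
        pa = condition_psth([_unit([[5.0]]), UnitSpikes("u1", 1,
                                                        [np.array([5.0, 6.0])])],
                            [trial], {"all": cell()}, width=0.0)
        pop = population_average(pa)
        at5 = pop.loc[pop["bin_center_ms"] == 5.0, "mean_rate"].iloc[0]
        assert at5 == pytest.approx((100.0 + 200.0) / 2.0)

    def test_single_unit_rejected(self):
        trial = _trial()
        p = condition_psth([_unit([[5.0]])], [trial], {"all": cell()},
                           width=0.0)
        with pytest.raises(ValueError, match="at least 2"):
            population_average(p)


def test_moving_mean_edge_bins_use_partial_window():
    x = np.zeros(20)
    x[0] = 10.0
    sm = moving_mean(x, 100.0)
    assert sm[0] == pytest.approx(10.0 / 6.0)   # bins 0..5 available
    assert sm[5] == pytest.approx(10.0 / 11.0)
    assert sm[6] == 0.0
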