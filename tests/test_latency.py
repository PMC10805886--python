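"""Run-of-5 latency criterion and the neuron-level bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncelab.latency import (RESOLUTION_MIN_LATENCY, bootstrap_latency,
                            detection_latency, first_run_start,
                            resolution_latency)

GRID = np.arange(-100.0, 1600.0, 10.0)  # detection bin left edges


def _brute_force_first_run(sig, run_length=5):
    for i in range(len(sig) - run_length + 1):
        if all(sig[i:i + run_length]):
            return i
    return None


@settings(deadline=None, max_examples=300, derandomize=True)
@given(st.lists(st.booleans(), min_size=0, max_size=60))
def test_run_scan_matches_exhaustive_search(track):
    assert first_run_start(np.array(track, dtype=bool)) == \
        _brute_force_first_run(track)


def _matrix_with_onset(onset_bin, n_units=12, amplitude=1.0, noise=0.0,
                       rng=None, n_bins=GRID.size):
    mat = np.zeros((n_units, n_bins))
    mat[:, onset_bin:] = amplitude
    if noise and rng is not None:
        mat += rng.normal(0.0, noise, mat.shape)
    return mat


class TestDetection:
    def test_all_zero_matrix_is_censored(self):
        res = detection_latency(np.zeros((10, GRID.size)), GRID)
        assert res.censored and res.latency_ms is None

    def test_clean_onset_recovered_exactly(self):
        for k in (0, 3, 40, 100):
            mat = _matrix_with_onset(k)
            res = detection_latency(mat, GRID)
            assert res.latency_ms == GRID[k]

    def test_four_bin_run_is_censored(self):
        mat = np.zeros((12, GRID.size))
        mat[:, 20:24] = 1.0   # 4 significant bins, then a gap
        mat[:, 25:28] = 1.0
        res = detection_latency(mat, GRID)
        assert res.censored

    def test_fewer_than_five_units_rejected(self):
        with pytest.raises(ValueError, match="5 units"):
            detection_latency(np.zeros((4, GRID.size)), GRID)

    def test_fewer_than_five_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            detection_latency(np.ones((10, 3)), GRID[:3])

    def test_consistency_at_large_effect(self):
        """Latency converges to the generative onset with n and amplitude."""
        onset_bin = 19  # grid value 90 ms
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mat = _matrix_with_onset(onset_bin, n_units=100, amplitude=5.0,
                                     noise=8.0, rng=rng)
            res = detection_latency(mat, GRID)
            assert abs(res.latency_ms - GRID[onset_bin]) <= 10.0

    def test_type_one_control_on_null_matrices(self):
        censored = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            mat = rng.normal(0.0, 1.0, (60, GRID.size))
            censored += detection_latency(mat, GRID).censored
        assert censored >= 80


class TestResolution:
    RGRID = np.arange(-100.0, 1600.0, 10.0)

    def test_no_selection_is_censored(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(0.0, 1.0, (60, self.RGRID.size))
        res = resolution_latency(mat, self.RGRID)
        assert res.censored

    def test_negative_signal_never_qualifies(self):
        mat = np.full((12, self.RGRID.size), -1.0)
        res = resolution_latency(mat, self.RGRID)
        assert res.censored  # significance without positivity is not enough

    def test_early_onset_left_censored_at_410(self):
        mat = np.zeros((12, self.RGRID.size))
        mat[:, self.RGRID >= 200.0] = 2.0
        res = resolution_latency(mat, self.RGRID)
        assert res.latency_ms == RESOLUTION_MIN_LATENCY
        assert res.left_censored

    def test_in_window_onset_recovered(self):
        mat = np.zeros((12, self.RGRID.size))
        mat[:, self.RGRID >= 800.0] = 2.0
        res = resolution_latency(mat, self.RGRID)
        # centered smoothing spreads the step backward by <= 50 ms
        assert not res.censored
        assert 750.0 <= res.latency_ms <= 810.0
        res_raw = resolution_latency(mat, self.RGRID, smooth_width=0.0)
        assert res_raw.latency_ms == 800.0


class TestBootstrap:
    def test_smoke_run_records_ten_replicates(self):
        mat = _matrix_with_onset(30)
        est = bootstrap_latency(mat, GRID, "detection", n_boot=10, seed=1)
        assert est.boot.size == 10
        assert est.n_boot == 10

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        mat = _matrix_with_onset(30, n_units=20, amplitude=2.0, noise=1.0,
                                 rng=rng)
        a = bootstrap_latency(mat, GRID, "detection", n_boot=50, seed=9)
        b = bootstrap_latency(mat, GRID, "detection", n_boot=50, seed=9)
        assert np.array_equal(a.boot, b.boot, equal_nan=True)
        assert a.median == b.median

    def test_homogeneous_cohort_has_tight_iqr(self):
        rng = np.random.default_rng(6)
        mat = _matrix_with_onset(19, n_units=60, amplitude=5.0, noise=4.0,
                                 rng=rng)
        est = bootstrap_latency(mat, GRID, "detection", n_boot=300, seed=2)
        assert est.iqr <= 20.0
        assert est.median == pytest.approx(GRID[19], abs=10.0)

    def test_fully_censored_reports_censored_median(self):
        mat = np.zeros((10, GRID.size))
        est = bootstrap_latency(mat, GRID, "detection", n_boot=20, seed=3)
        assert est.censored_fraction == 1.0
        assert np.isnan(est.median)

    def test_bimodal_mixture_detected(self):
        """Two disjoint onset subpopulations produce a bimodal bootstrap.

        An 8-unit early-onset minority makes the full-sample early run
        marginal, so replicates split between the early and late modes.
        """
        rng = np.random.default_rng(7)
        early = _matrix_with_onset(20, n_units=8, amplitude=5.0, noise=1.0,
                                   rng=rng)
        late = _matrix_with_onset(120, n_units=16, amplitude=5.0, noise=1.0,
                                  rng=rng)
        mat = np.vstack([early, late])
        est = bootstrap_latency(mat, GRID, "detection", n_boot=400, seed=4)
        ok = est.boot[np.isfinite(est.boot)]
        near_early = np.mean(np.abs(ok - GRID[20]) <= 30.0)
        near_late = np.mean(np.abs(ok - GRID[120]) <= 30.0)
        assert near_early > 0.2 and near_late > 0.1
        assert GRID[20] <= est.median <= GRID[120]
        assert est.iqr >= 20.0  # dispersion reflects the mixture
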