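import numpy as np
import pytest

import speedcells as sc
from speedcells import kinematics as kin

from conftest import make_track, make_trials


def _track_from_x(x, dt=0.1):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) * dt
    return sc.PositionTrack(t, x, np.zeros_like(x), dt=dt)


class TestSmoothing:
    def test_constant_track_is_fixed_point(self):
        tr = _track_from_x(np.full(10, 3.5))
        sm = sc.smooth_positions(tr)
        np.testing.assert_allclose(sm.x, tr.x)

    def test_linear_ramp_center_unchanged(self):
        sm = sc.smooth_positions(_track_from_x([0, 1, 2, 3, 4, 5]))
        assert sm.x[2] == pytest.approx(2.0)
        assert sm.x[3] == pytest.approx(3.0)

    def test_impulse_spread_to_one_fifth(self):
        sm = sc.smooth_positions(_track_from_x([0, 0, 5, 0, 0, 0]))
        assert sm.x[2] == pytest.approx(1.0)

    def test_length_preserved(self):
        sm = sc.smooth_positions(make_track())
        assert sm.n_samples == make_track().n_samples


class TestSpeed:
    def test_stationary_track_zero_speed(self):
        tr = _track_from_x(np.zeros(20))
        assert np.all(sc.compute_speed(tr).speed == 0)

    def test_three_four_five_triangle(self):
        # 0.3 cm in x and 0.4 cm in y per 0.1-s step -> 5 cm/s
        n = 10
        t = np.arange(n) * 0.1
        tr = sc.PositionTrack(t, 0.3 * np.arange(n), 0.4 * np.arange(n), dt=0.1)
        np.testing.assert_allclose(sc.compute_speed(tr).speed, 5.0)

    def test_paper_sampling_rate_units(self):
        # 0.256 cm per 0.0256-s sample is 10 cm/s
        n = 50
        t = np.arange(n) * 0.0256
        tr = sc.PositionTrack(t, 0.256 * np.arange(n), np.zeros(n))
        np.testing.assert_allclose(sc.compute_speed(tr).speed, 10.0)

    def test_midpoint_timestamps_and_length(self):
        tr = make_track(duration=1.0, dt=0.1)
        sp = sc.compute_speed(tr)
        assert sp.speed.size == tr.n_samples - 1
        np.testing.assert_allclose(sp.timestamps[0], 0.05)


class TestMasking:
    @pytest.fixture
    def speed10(self):
        # 10 s of 10 cm/s at 0.1-s sampling with two spoiled samples
        tr = _track_from_x(np.arange(101, dtype=float))  # 10 cm/s
        sp = sc.compute_speed(tr)
        sp.speed[30] = 75.0  # mistracking spike
        sp.speed[40] = 0.0  # frozen tracking
        return sp

    def test_mask_rules(self, speed10):
        trials = make_trials([(0.0, 6.0), (7.0, 10.0)])
        m = sc.mask_epochs(speed10, trials)
        assert not m.valid_mask[30]  # above 60 cm/s inside a trial
        assert not m.valid_mask[40]  # exactly zero inside a trial
        between = (m.timestamps >= 6.0) & (m.timestamps < 7.0)
        assert not m.valid_mask[between].any()  # outside task epochs
        assert m.valid_mask[10]  # ordinary in-trial sample survives

    def test_threshold_boundary_inclusive(self, speed10):
        speed10.speed[:] = 60.0
        m = sc.mask_epochs(speed10, make_trials([(0.0, 10.0)]))
        assert m.valid_mask.all()  # exactly 60 cm/s is kept (rule is > 60)

    def test_empty_trials_rejected(self, speed10):
        with pytest.raises(sc.ValidationError):
            sc.mask_epochs(speed10, make_trials([]).select(np.zeros(0, bool)))

    def test_mask_monotone_in_max_speed(self, small_session):
        bundle, _ = small_session
        sp = sc.speed_from_track(bundle.position)
        counts = [sc.mask_epochs(sp, bundle.trials, mx).n_valid
                  for mx in (60.0, 40.0, 20.0, 10.0)]
        assert counts == sorted(counts, reverse=True)


class TestBinning:
    def _uniform_pair(self, duration=10.0, rate_hz=5):
        tr = _track_from_x(np.arange(int(duration * 10) + 1, dtype=float))
        sp = sc.compute_speed(tr)
        spikes = np.arange(0, duration, 1.0 / rate_hz) + 1e-3
        return sp, sc.SpikeTrain("u", spikes, "MSN")

    def test_window_count_ten_seconds(self):
        sp, u = self._uniform_pair(10.0)
        b = sc.bin_pair(sp, u)
        assert b.n_bins == 91  # floor((10-1)/0.1)+1

    def test_rate_definition(self):
        sp, _ = self._uniform_pair(10.0)
        u = sc.SpikeTrain("u", [3.1, 3.2, 3.5, 3.7, 3.9], "MSN")
        b = sc.bin_pair(sp, u, overlap_s=0.0)
        assert b.rate_binned[3] == pytest.approx(5.0)  # 5 spikes in bin [3,4)

    def test_disjoint_binning_conserves_spike_count(self):
        sp, u = self._uniform_pair(10.0, rate_hz=7)
        b = sc.bin_pair(sp, u, overlap_s=0.0)
        assert np.sum(b.rate_binned * b.bin_s) == u.n_spikes

    def test_windows_do_not_bridge_gaps(self):
        sp, u = self._uniform_pair(10.0)
        sp.valid_mask[50] = False  # 0.1-s hole at t=5
        b = sc.bin_pair(sp, u)
        assert len(np.unique(b.seg_ids)) == 2
        # no window may contain the invalid sample's time
        bad = np.abs(b.bin_centers - sp.timestamps[50]) < 0.5
        assert not bad.any()

    def test_no_valid_window_returns_empty(self):
        sp, u = self._uniform_pair(10.0)
        sp.valid_mask[:] = False
        assert sc.bin_pair(sp, u).is_empty


class TestZScore:
    def test_population_sd_three_points(self):
        b = kin.BinnedPair(np.arange(3.0), np.array([1.0, 2.0, 3.0]),
                           np.array([1.0, 2.0, 3.0]), np.zeros(3, int))
        z = sc.zscore_pair(b)
        np.testing.assert_allclose(z.speed_z, [-1.2247448, 0.0, 1.2247448],
                                   atol=1e-6)

    def test_constant_series_degenerate(self):
        b = kin.BinnedPair(np.arange(3.0), np.ones(3), np.array([1.0, 2.0, 3.0]),
                           np.zeros(3, int))
        with pytest.raises(sc.DegenerateSeriesError):
            sc.zscore_pair(b)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        b = kin.BinnedPair(np.arange(50.0), x, rng.normal(size=50),
                           np.zeros(50, int))
        z1 = sc.zscore_pair(b)
        b2 = kin.BinnedPair(z1.bin_centers, z1.speed_z, z1.rate_z, z1.seg_ids)
        z2 = sc.zscore_pair(b2)
        np.testing.assert_allclose(z2.speed_z, z1.speed_z, atol=1e-12)
        assert abs(z1.speed_z.mean()) < 1e-10
        assert abs(z1.speed_z.std() - 1) < 1e-10


class TestUnitInclusion:
    @pytest.mark.parametrize("rate_hz,kept", [(0.4, False), (0.6, True),
                                              (0.5, False)])
    def test_rate_threshold_strict(self, rate_hz, kept):
        tr = _track_from_x(np.arange(1001, dtype=float))  # 100 s valid
        sp = sc.compute_speed(tr)
        n = int(rate_hz * 100)
        u = sc.SpikeTrain("u", np.linspace(0.01, 99.9, n), "MSN")
        included, excluded = sc.filter_units([u], sp)
        assert (len(included) == 1) == kept
        if not kept:
            assert excluded[0][0] == "u"


def test_recomputed_speed_matches_generator_truth(small_session):
    """Kinematics recovers the generator's true speed to < 5% RMS of the mean
    (residual is smoothing attenuation only)."""
    bundle, truth = small_session
    sp = sc.speed_from_track(bundle.position)
    # compare away from injected artifacts
    ok = np.ones(sp.speed.size, bool)
    for ta in truth.artifact_times:
        ok &= np.abs(sp.timestamps - ta) > 0.5
    rms = np.sqrt(np.mean((sp.speed[ok] - truth.true_speed[ok]) ** 2))
    assert rms < 0.05 * truth.true_speed.mean()
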