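import numpy as np
import pytest

import speedcells as sc
from speedcells import decoding as dec


def prepared(rate, speed, seg=None):
    rate = np.asarray(rate, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if seg is None:
        seg = np.zeros(rate.size, dtype=int)
    return dec.PreparedSeries(np.arange(rate.size, dtype=float), rate, speed,
                              seg, rate_raw=rate, speed_raw=speed)


def smooth_rate(n=300):
    t = np.arange(n, dtype=float)
    return 3 + np.sin(2 * np.pi * t / 60) + 0.5 * np.sin(2 * np.pi * t / 37)


class TestWinsorize:
    def test_caps_at_linear_interpolation_p95(self):
        x = np.arange(1.0, 101.0)
        capped = dec.winsorize_upper(x)
        assert capped.max() == pytest.approx(np.percentile(x, 95))
        assert capped.min() == 1.0  # lower tail untouched

    def test_idempotent(self):
        # n chosen so the interpolated 95th percentile lands exactly on an
        # order statistic, where capping is an exact fixed point
        rng = np.random.default_rng(0)
        x = rng.exponential(2.0, 501)
        once = dec.winsorize_upper(x)
        np.testing.assert_array_equal(dec.winsorize_upper(once), once)

    def test_all_equal_unchanged(self):
        x = np.full(50, 7.0)
        np.testing.assert_array_equal(dec.winsorize_upper(x), x)


class TestGaussianSmooth:
    def test_constant_fixed_point(self):
        x = np.full(40, 2.5)
        np.testing.assert_allclose(dec.gaussian_smooth(x), x, atol=1e-12)

    def test_no_bleed_across_segments(self):
        x = np.concatenate([np.zeros(30), np.full(30, 10.0)])
        seg = np.repeat([0, 1], 30)
        sm = dec.gaussian_smooth(x, seg)
        np.testing.assert_allclose(sm[:30], 0.0, atol=1e-12)
        np.testing.assert_allclose(sm[30:], 10.0, atol=1e-12)

    def test_short_segment_handled(self):
        x = np.arange(5.0)
        np.testing.assert_allclose(dec.gaussian_smooth(x).mean(), x.mean(),
                                   atol=0.2)


def test_contiguous_fold_partition():
    for n in (95, 100, 103):
        folds = dec.contiguous_folds(n, 10)
        sizes = [f.size for f in folds]
        assert max(sizes) - min(sizes) <= 1
        np.testing.assert_array_equal(np.concatenate(folds), np.arange(n))


class TestDecodeSingle:
    def test_noiseless_linear_map(self):
        rate = smooth_rate()
        res = dec.decode_single(prepared(rate, 2 + 3 * rate), "u")
        assert res.r2 >= 0.99

    def test_noiseless_monotone_cubic_map(self):
        rate = smooth_rate()
        res = dec.decode_single(prepared(rate, 1 + 0.5 * rate + 0.2 * rate ** 3),
                                "u")
        assert res.r2 >= 0.99

    def test_uninformative_rate_near_or_below_zero(self):
        rng = np.random.default_rng(1)
        res = dec.decode_single(
            prepared(rng.poisson(5, 300).astype(float), 2 + 3 * smooth_rate()),
            "u")
        assert res.r2 <= 0.05

    def test_constant_rate_nan_with_reason(self):
        res = dec.decode_single(prepared(np.full(100, 4.0), smooth_rate(100)),
                                "u")
        assert np.isnan(res.r2)
        assert "constant" in res.reason

    def test_r2_is_mean_of_folds(self):
        rate = smooth_rate()
        res = dec.decode_single(prepared(rate, 2 + 3 * rate), "u")
        assert res.r2 == pytest.approx(res.fold_r2.mean())
        assert len(res.fold_r2) == 10

    def test_too_few_bins_skipped(self, small_speed):
        short = sc.SpeedSeries(small_speed.timestamps[:100],
                               small_speed.speed[:100],
                               small_speed.valid_mask[:100], small_speed.dt)
        with pytest.raises(sc.AnalysisSkipped):
            dec.prepare_decoding_series(short, sc.SpikeTrain("u", [0.5], "MSN"))


class TestChance:
    def test_deterministic_given_seed(self):
        rate = smooth_rate()
        p = prepared(rate, 2 + 3 * rate + 0.1 * np.arange(300))
        a = dec.chance_level(p, "u", n_rep=10, seed=5)
        b = dec.chance_level(p, "u", n_rep=10, seed=5)
        assert a == b

    def test_informative_unit_beats_chance(self, small_speed, small_session):
        bundle, _ = small_session
        prep = dec.prepare_decoding_series(small_speed, bundle.units[0])
        res = dec.decode_single(prep, "u000")
        ch = dec.chance_level(prep, "u000", n_rep=20, seed=2)
        assert res.r2 > ch


class TestDecodeMulti:
    def test_single_unit_ridge_close_to_ols(self, small_speed, small_session):
        bundle, _ = small_session
        prep = dec.prepare_decoding_series(small_speed, bundle.units[0])
        ols = dec.decode_single(prep, "u000").r2
        df = dec.decode_multi(prep.rate_raw[:, None], prep.speed_raw,
                              prep.seg_ids, ["u000"], k_max=1, seed=0,
                              r2_gate=-np.inf)
        assert abs(df["r2"].iloc[0] - ols) < 0.05

    def test_duplicated_unit_stays_finite(self):
        rate = smooth_rate()
        speed = 2 + 3 * rate
        cols = np.column_stack([rate, rate])  # perfect collinearity
        df = dec.decode_multi(cols, speed, np.zeros(rate.size, int),
                              ["a", "b"], k_max=2, seed=0)
        assert np.isfinite(df["r2"]).all()
        assert df[df.k == 2]["r2"].iloc[0] > 0.9

    def test_gate_excludes_weak_units(self):
        rng = np.random.default_rng(2)
        rate = smooth_rate()
        noise = rng.poisson(5, 300).astype(float)
        cols = np.column_stack([rate, noise])
        df = dec.decode_multi(cols, 2 + 3 * rate, np.zeros(300, int),
                              ["good", "bad"], k_max=2, seed=0)
        assert set(df["unit_ids"]) == {"good"}

    def test_no_eligible_units_skipped(self):
        rng = np.random.default_rng(3)
        cols = rng.poisson(5, (300, 2)).astype(float)
        with pytest.raises(sc.AnalysisSkipped):
            dec.decode_multi(cols, 2 + 3 * smooth_rate(), np.zeros(300, int),
                             ["a", "b"], k_max=2, seed=0)

    def test_common_shift_surrogates_reported(self):
        rate = smooth_rate()
        df = dec.decode_multi(np.column_stack([rate]), 2 + 3 * rate,
                              np.zeros(300, int), ["a"], k_max=1,
                              n_chance=5, seed=1)
        assert np.isfinite(df["chance_r2"]).all()
        assert df["r2"].iloc[0] > df["chance_r2"].iloc[0]


def test_train_fold_cap_applied_to_test_outliers():
    """Leakage guard: a huge outlier confined to one fold must be capped at
    the training folds' percentile, leaving prediction accuracy intact."""
    rate = smooth_rate()
    speed = 2 + 3 * rate
    rate_out = rate.copy()
    rate_out[295:] = 1000.0  # outlier burst inside the final fold only
    res = dec.decode_single(prepared(rate_out, speed), "u")
    assert np.all(res.fold_r2[:9] > 0.85)
    assert np.mean(res.fold_r2[:9]) > 0.9
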