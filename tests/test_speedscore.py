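import numpy as np
import pytest
from scipy.stats import pearsonr

import speedcells as sc
from speedcells.kinematics import ZScoredPair
from speedcells import speedscore as sps


def zscore(x):
    return (x - x.mean()) / x.std()


def make_zpair(speed, rate, seg=None, stride=0.1):
    speed = np.asarray(speed, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if seg is None:
        seg = np.zeros(speed.size, dtype=int)
    return ZScoredPair(np.arange(speed.size) * stride, zscore(speed),
                       zscore(rate), np.asarray(seg), stride)


def oracle_ccg(rate, speed, k):
    """Brute-force shift-trim-Pearson reference for gapless series."""
    L = rate.size
    if k >= 0:
        a, b = rate[k:], speed[:L - k] if k else speed
    else:
        a, b = rate[:L + k], speed[-k:]
    return pearsonr(a, b)[0]


class TestCrossCorrelogram:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        z = make_zpair(x, x)
        score, lag = sc.speed_score(sc.cross_correlogram(z))
        assert score == pytest.approx(1.0)
        assert lag == 0.0

    def test_anticorrelation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        score, lag = sc.speed_score(sc.cross_correlogram(make_zpair(x, -x)))
        assert score == pytest.approx(-1.0)
        assert lag == 0.0

    def test_delayed_rate_gives_positive_lag(self):
        """Rate = speed delayed by 7 strides -> peak at +0.7 s, matching the
        brute-force oracle at every lag."""
        rng = np.random.default_rng(3)
        speed = rng.normal(size=800)
        rate = np.roll(speed, 7)
        z = make_zpair(speed, rate)
        ccg = sc.cross_correlogram(z)
        for lag, r in zip(ccg.lags, ccg.r):
            k = int(round(lag / z.stride))
            assert r == pytest.approx(oracle_ccg(z.rate_z, z.speed_z, k),
                                      abs=1e-9)
        score, lag = sc.speed_score(ccg)
        assert lag == pytest.approx(0.7)

    def test_gap_pairs_excluded(self):
        """Pairs spanning two segments never enter the correlation."""
        rng = np.random.default_rng(4)
        speed = rng.normal(size=400)
        rate = rng.normal(size=400)
        seg = np.repeat([0, 1], 200)
        ccg = sc.cross_correlogram(make_zpair(speed, rate, seg))
        k10 = np.flatnonzero(np.isclose(ccg.lags, 1.0))[0]
        assert ccg.n_pairs[k10] == 2 * (200 - 10)

    def test_too_few_pairs_degenerate(self):
        z = make_zpair(np.arange(10.0), np.arange(10.0) ** 2)
        with pytest.raises(sc.DegenerateSeriesError):
            sc.cross_correlogram(z)


class TestPeakSelection:
    def test_plain_argmax(self):
        ccg = sps.CCG(np.array([-0.1, 0.0, 0.1]), np.array([0.1, 0.46, 0.2]),
                      np.full(3, 100))
        assert sc.speed_score(ccg) == (0.46, 0.0)

    def test_absolute_peak_carries_sign(self):
        ccg = sps.CCG(np.array([-0.1, 0.0, 0.1]), np.array([-0.33, 0.1, 0.2]),
                      np.full(3, 100))
        assert sc.speed_score(ccg) == (-0.33, -0.1)

    def test_tie_breaks_toward_zero_then_negative(self):
        ccg = sps.CCG(np.array([-0.2, 0.1, 0.3]), np.array([0.4, 0.4, 0.2]),
                      np.full(3, 100))
        assert sc.speed_score(ccg)[1] == pytest.approx(0.1)  # closer to 0
        ccg = sps.CCG(np.array([-0.1, 0.1]), np.array([0.4, 0.4]),
                      np.full(2, 100))
        assert sc.speed_score(ccg)[1] == pytest.approx(-0.1)  # exact tie


class TestSurrogates:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        z = make_zpair(rng.normal(size=600), rng.normal(size=600))
        a = sc.surrogate_null(z, n_surr=50, seed=9)
        b = sc.surrogate_null(z, n_surr=50, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_null_mirrors_under_rate_negation(self):
        """Negating the rate series exactly negates every surrogate score
        (sign symmetry of the null)."""
        rng = np.random.default_rng(6)
        speed, rate = rng.normal(size=1500), rng.normal(size=1500)
        z = make_zpair(speed, rate)
        z_neg = make_zpair(speed, -rate)
        a = sc.surrogate_null(z, n_surr=100, seed=1)
        b = sc.surrogate_null(z_neg, n_surr=100, seed=1)
        np.testing.assert_allclose(b, -a, atol=1e-12)

    def test_short_series_rejected(self):
        rng = np.random.default_rng(7)
        z = make_zpair(rng.normal(size=60), rng.normal(size=60))
        with pytest.raises(sc.ValidationError):
            sc.surrogate_null(z, n_surr=10, seed=0)  # 20% of 60 < 50-stride lag window


class TestClassification:
    def test_two_sd_rule_arithmetic(self):
        rng = np.random.default_rng(8)
        surr = rng.normal(0.0, 0.05, 5000)
        hit = sc.classify_unit("u", 0.30, 0.0, surr)
        miss = sc.classify_unit("u", 0.08, 0.0, surr)
        assert hit.exceeds_2sd and hit.p_emp < 0.01
        assert not miss.exceeds_2sd
        assert miss.sign == "positive"

    def test_negative_score_flagged_symmetrically(self):
        rng = np.random.default_rng(9)
        surr = rng.normal(0.0, 0.05, 5000)
        res = sc.classify_unit("u", -0.30, -0.2, surr)
        assert res.exceeds_2sd and res.sign == "negative"

    def test_score_inside_null_has_p_one(self):
        surr = np.concatenate([np.full(500, 0.4), np.full(500, -0.4)])
        res = sc.classify_unit("u", 0.1, 0.0, surr)
        assert res.p_emp == 1.0
        assert not res.exceeds_2sd

    def test_constant_surrogates_degenerate(self):
        with pytest.raises(sc.DegenerateSeriesError):
            sc.classify_unit("u", 0.3, 0.0, np.full(1000, 0.3))


class TestFDR:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(sc.fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert sc.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_ones_fixed_point(self):
        np.testing.assert_allclose(sc.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(sc.ValidationError):
            sc.fdr_adjust([0.5, 1.5])


@pytest.mark.parametrize("score,expected", [
    (0.15, "weak"), (-0.30, "moderate"), (0.45, "strong"),
    (0.2, "moderate"), (0.4, "moderate"), (-0.41, "strong"),
])
def test_strength_bands(score, expected):
    assert sc.strength_class(score) == expected


def test_sign_recovery_and_mirror_symmetry(small_session):
    """Positive- and negative-gain units score with matching signs; the null
    unit scores well below both."""
    bundle, truth = small_session
    scores, _ = sc.score_session(bundle, n_surr=300, seed=3)
    by_id = scores.set_index("unit_id")
    assert by_id.loc["u000", "score"] > 0.2
    assert by_id.loc["u001", "score"] < -0.15
    assert abs(by_id.loc["u002", "score"]) < abs(by_id.loc["u000", "score"])
    assert by_id.loc["u000", "sign"] == "positive"
    assert by_id.loc["u001", "sign"] == "negative"
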