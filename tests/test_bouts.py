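import numpy as np
import pytest

import speedcells as sc
from speedcells import bouts as bts


def trace(v, dt=0.1):
    """(t, v, seg) triple on the 0.1-s grid, one segment."""
    v = np.asarray(v, dtype=float)
    t = np.arange(v.size) * dt + dt / 2
    return t, v, np.zeros(v.size, dtype=int)


def steps(*segments):
    """Concatenate (duration_s, speed) plateaus into a sample array."""
    return np.concatenate([np.full(int(round(d / 0.1)), s)
                           for d, s in segments])


def oracle_detect(t, v, kind, v_thresh=5.0):
    """Independent exhaustive enumeration of the 2 s + 5 s window rule with
    the earliest-candidate / skip-the-window resolution."""
    events = []
    i = 0
    while i + 70 <= v.size:
        pre, post = v[i:i + 20], v[i + 20:i + 70]
        if kind == "onset":
            ok = np.all(pre < v_thresh) and np.sum(post > v_thresh) >= 25
        else:
            ok = np.all(pre > v_thresh) and np.sum(post < v_thresh) >= 25
        if ok:
            events.append(t[i + 20] - 0.05)
            i += 70
        else:
            i += 1
    return events


class TestDetector:
    def test_step_trace_single_onset_matches_oracle(self):
        t, v, seg = trace(steps((3.0, 0.0), (6.0, 20.0)))
        got = sc.detect_bouts((t, v, seg), "onset")
        assert [e.t_ref for e in got] == oracle_detect(t, v, "onset")
        assert len(got) == 1

    def test_constant_trace_no_events(self):
        t, v, seg = trace(np.full(120, 10.0))
        assert sc.detect_bouts((t, v, seg), "onset") == []
        assert sc.detect_bouts((t, v, seg), "offset") == []

    def test_short_blip_rejected_by_persistence(self):
        # 1-s blip covers 20% of the post-window, below the 50% requirement
        t, v, seg = trace(steps((5.0, 0.0), (1.0, 20.0), (6.0, 0.0)))
        assert sc.detect_bouts((t, v, seg), "onset") == []

    def test_exact_threshold_counts_for_neither(self):
        t, v, seg = trace(steps((3.0, 5.0), (6.0, 20.0)))
        assert sc.detect_bouts((t, v, seg), "onset") == []  # pre not < 5

    def test_same_kind_events_separated_by_window(self):
        v = steps(*([(2.5, 0.0), (5.0, 20.0)] * 6))
        t, v, seg = trace(v)
        ev = sc.detect_bouts((t, v, seg), "onset")
        assert len(ev) >= 2
        assert np.all(np.diff([e.t_ref for e in ev]) >= 7.0 - 1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        v = np.concatenate([
            np.full(rng.integers(15, 80),
                    rng.choice([0.5, 2.0, 8.0, 20.0]))
            for _ in range(30)
        ])
        t, vv, seg = trace(v)
        for kind in ("onset", "offset"):
            got = [e.t_ref for e in sc.detect_bouts((t, vv, seg), kind)]
            assert got == pytest.approx(oracle_detect(t, vv, kind))

    @pytest.mark.parametrize("seed", range(4))
    def test_mirror_symmetry_on_clean_plateaus(self, seed):
        """Time reversal maps onsets to offsets one-to-one when every plateau
        outlasts the 7-s window."""
        rng = np.random.default_rng(100 + seed)
        v = steps(*[(float(rng.uniform(7.5, 12.0)), s)
                    for _ in range(6) for s in (0.0, 20.0)])
        t, vv, seg = trace(v)
        n_on = len(sc.detect_bouts((t, vv, seg), "onset"))
        tr, vr, segr = trace(vv[::-1])
        n_off_rev = len(sc.detect_bouts((tr, vr, segr), "offset"))
        assert n_on == n_off_rev >= 1

    def test_detection_confined_to_segments(self):
        # a masked gap through the transition suppresses the event
        t, v, seg = trace(steps((3.0, 0.0), (6.0, 20.0)))
        seg2 = seg.copy()
        seg2[30:] = 1  # break exactly at the step
        assert sc.detect_bouts((t, v, seg2), "onset") == []


class TestPSTH:
    def test_single_spike_normalization_arithmetic(self):
        # one event, one spike: its 0.1-s bin reads 70, all others 0, mean 1
        u = sc.SpikeTrain("u", [10.03], "MSN")
        p = sc.event_psth(u, [bts.BoutEvent("onset", 10.0)])
        assert p.norm_rate.max() == pytest.approx(70.0)
        assert p.norm_rate.mean() == pytest.approx(1.0, abs=1e-10)
        assert p.n_events == 1

    def test_every_retained_event_mean_is_one(self):
        rng = np.random.default_rng(3)
        u = sc.SpikeTrain("u", np.sort(rng.uniform(0, 500, 2000)), "MSN")
        events = [bts.BoutEvent("onset", t0) for t0 in range(10, 480, 15)]
        for ev in events:
            single = sc.event_psth(u, [ev])
            assert single.norm_rate.mean() == pytest.approx(1.0, abs=1e-10)

    def test_constant_rate_unit_flat_psth(self):
        """A homogeneous 10-Hz Poisson unit yields norm rate ~ 1 everywhere."""
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(0, 2000, 20_000))  # 10 Hz over 2000 s
        u = sc.SpikeTrain("u", spikes, "MSN")
        events = [bts.BoutEvent("onset", t0) for t0 in range(5, 1990, 10)]
        p = sc.event_psth(u, events)
        z = np.abs(p.norm_rate - 1.0) / p.sem
        # at most the chance-expected number of bins beyond 3 SEM
        assert int(np.sum(z > 3)) <= 2
        assert z.mean() < 1.5

    def test_zero_spike_events_excluded_and_counted(self):
        u = sc.SpikeTrain("u", [10.0, 10.5], "MSN")
        events = [bts.BoutEvent("onset", 10.0), bts.BoutEvent("onset", 100.0)]
        p = sc.event_psth(u, events)
        assert p.n_events == 1
        assert p.n_excluded == 1

    def test_no_events_degenerate(self):
        u = sc.SpikeTrain("u", [1.0], "MSN")
        with pytest.raises(sc.DegenerateSeriesError):
            sc.event_psth(u, [])

    def test_positive_gain_unit_ramps_at_onset(self, small_session):
        bundle, _ = small_session
        sp = sc.speed_from_track(bundle.position)
        rs = sc.resample_speed(sp)
        events = sc.detect_bouts(rs, "onset")
        assert len(events) >= 3
        p = sc.event_psth(bundle.units[0], events, speed=rs)
        assert p.norm_rate[20:].mean() > p.norm_rate[:20].mean()
        # the aligned speed trace itself crosses the threshold at time 0
        assert p.speed_mean[:20].mean() < 5.0 < p.speed_mean[25:].mean()
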