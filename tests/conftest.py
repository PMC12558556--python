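import numpy as np
import pytest

import speedcells as sc


def make_track(duration=10.0, dt=0.0256, vx=10.0, vy=0.0):
    """Straight-line constant-velocity track (cm, cm/s)."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    return sc.PositionTrack(t, vx * t, vy * t, dt=dt)


def make_trials(bounds, cue=None, choice=None, outcome=None):
    """Trial table from a list of (t_start, t_end), labels cycled if not given."""
    n = len(bounds)
    starts = np.array([b[0] for b in bounds], dtype=float)
    ends = np.array([b[1] for b in bounds], dtype=float)
    cue = cue or [("visual", "spatial")[i % 2] for i in range(n)]
    choice = choice or [("left", "right")[i % 2] for i in range(n)]
    outcome = outcome or [("rewarded", "non_rewarded")[i % 3 == 2] for i in range(n)]
    return sc.TrialTable(np.arange(1, n + 1), starts, ends,
                         np.array(cue, dtype=object),
                         np.array(choice, dtype=object),
                         np.array(outcome, dtype=object))


@pytest.fixture(scope="session")
def small_session():
    """300-s synthetic session: one positive, one negative, one null unit."""
    cfg = sc.SynthConfig(
        duration=300.0, n_trials=30,
        units=[
            sc.UnitSpec(baseline_rate=5.0, gain=0.2, coupling_lag=0.0,
                        cell_type="MSN"),
            sc.UnitSpec(baseline_rate=10.0, gain=-0.15, coupling_lag=0.0,
                        cell_type="FSI"),
            sc.UnitSpec(baseline_rate=5.0, gain=0.0, cell_type="MSN"),
        ],
        seed=42,
    )
    return sc.generate_session(cfg)


@pytest.fixture(scope="session")
def small_speed(small_session):
    bundle, _ = small_session
    return sc.mask_epochs(sc.speed_from_track(bundle.position), bundle.trials)
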