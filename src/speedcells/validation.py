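"""Ground-truth validation studies for the whole pipeline.

Each study generates synthetic sessions under fixed, documented conditions,
runs the standard analysis path, and returns summary metrics: oracle
equivalence of the cross-correlogram, false-positive calibration of the
speed-cell and modulation tests, recovery of injected gains and lags,
bout-detector and PSTH behavior, and decoding performance including the
multi-cell population gain. The test suite asserts on these metrics; the
acceptance script reports them.

Study conditions (session length, rates, counts) are part of the validation
design, chosen once: null calibration uses two 600-s sessions of 100
independent 5-Hz Poisson units each with 1000 circular-shift surrogates per
unit; parameter recovery uses 900-s single-unit sessions with gain calibrated
to a realized rate-speed correlation of ~0.4; decoding studies use 600-s
sessions; the modulation studies use 400-s, 40-trial sessions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import bouts as bts
from . import decoding as dec
from . import kinematics as kin
from . import speedscore as sps
from . import stability as stab
from .dataio import SessionBundle
from .errors import AnalysisSkipped
from .synth import SynthConfig, UnitSpec, calibrate_gain, generate_session


def _child_seeds(seed: int, label: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([seed, label])
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2**31


def _session_zpairs(cfg: SynthConfig):
    bundle, truth = generate_session(cfg)
    speed = kin.mask_epochs(kin.speed_from_track(bundle.position), bundle.trials)
    pairs = [kin.zscore_pair(kin.bin_pair(speed, u)) for u in bundle.units]
    return bundle, truth, speed, pairs


# ---------------------------------------------------------------------------

def oracle_equivalence_study(n_pairs: int = 50, max_len: int = 2000,
                             seed: int = 0) -> dict:
    """Cross-correlogram vs brute-force shift-trim-Pearson on gapless series.

    Returns the worst absolute deviation over every lag of every pair and the
    fraction of pairs whose peak matches the oracle argmax.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    worst = 0.0
    peak_match = 0
    for _ in range(n_pairs):
        L = int(rng.integers(300, max_len + 1))
        # AR(1) series so the CCG has structure; random cross-coupling
        a = rng.uniform(0.0, 0.95)
        e1, e2 = rng.normal(size=(2, L))
        speed = np.empty(L)
        speed[0] = e1[0]
        for i in range(1, L):
            speed[i] = a * speed[i - 1] + e1[i]
        shift = int(rng.integers(-20, 21))
        rate = np.roll(speed, shift) * rng.uniform(-1, 1) + e2
        z = kin.ZScoredPair(
            np.arange(L) * 0.1,
            (speed - speed.mean()) / speed.std(),
            (rate - rate.mean()) / rate.std(),
            np.zeros(L, dtype=int), 0.1)
        ccg = sps.cross_correlogram(z)
        # independent oracle: explicit shift, trim, Pearson at every lag
        ref = np.full(ccg.lags.size, np.nan)
        for i, lag in enumerate(ccg.lags):
            k = int(round(lag / z.stride))
            if k >= 0:
                x, y = z.rate_z[k:], z.speed_z[:L - k] if k else z.speed_z
            else:
                x, y = z.rate_z[:L + k], z.speed_z[-k:]
            if x.size >= sps.N_MIN_PAIRS:
                ref[i] = stats.pearsonr(x, y)[0]
        ok = np.isfinite(ref) & np.isfinite(ccg.r)
        worst = max(worst, float(np.max(np.abs(ccg.r[ok] - ref[ok]))))
        score, lag = sps.speed_score(ccg)
        ref_peak = int(np.nanargmax(np.abs(ref)))
        peak_match += np.isclose(lag, ccg.lags[ref_peak]) and np.isclose(
            score, ref[ref_peak], atol=1e-9)
    return {"max_abs_err": worst, "peak_match_frac": peak_match / n_pairs,
            "n_pairs": n_pairs}


def null_calibration_study(n_units: int = 200, n_sessions: int = 2,
                           n_surr: int = 1000, duration: float = 600.0,
                           seed: int = 0) -> dict:
    """False-positive rate of the speed-cell test on speed-independent units.

    ``n_units`` 5-Hz Poisson units with zero gain, split over independent
    sessions; returns the fraction passing the +/-2 SD magnitude-null rule
    (pre-FDR) and the fraction classified as speed cells (post-FDR).
    """
    per = n_units // n_sessions
    seeds = _child_seeds(seed, 2, 2 * n_sessions)
    frames = []
    for s in range(n_sessions):
        cfg = SynthConfig(duration=duration,
                          units=[UnitSpec(baseline_rate=5.0, gain=0.0)
                                 for _ in range(per)],
                          seed=seeds[2 * s])
        bundle, _ = generate_session(cfg)
        scores, _ = sps.score_session(bundle, n_surr=n_surr,
                                      seed=seeds[2 * s + 1])
        frames.append(scores)
    allsc = pd.concat(frames, ignore_index=True)
    return {"pre_fdr_flagged_frac": float(allsc["exceeds_2sd"].mean()),
            "post_fdr_flagged_frac": float(allsc["is_speed_cell"].mean()),
            "n_units": int(len(allsc))}


def recovery_conditions(seed: int = 0) -> tuple[SynthConfig, float]:
    """The parameter-recovery session template and its calibrated gain."""
    base = SynthConfig(duration=900.0, n_trials=90)
    gain = calibrate_gain(0.4, baseline_rate=5.0, config=base,
                          seed=_child_seeds(seed, 3, 1)[0])
    return base, gain


def parameter_recovery_study(n_seeds: int = 20,
                             lags: tuple[float, ...] = (-0.5, 0.0, 0.5),
                             seed: int = 0) -> dict:
    """Sign and coupling-lag recovery at a realized correlation of ~0.4.

    For each injected lag, ``n_seeds`` single-unit 900-s sessions; reports
    the fraction with positive recovered score (sign) and with recovered lag
    within +/-0.2 s (two bin strides), per condition and worst-case.
    """
    base, gain = recovery_conditions(seed)
    seeds = _child_seeds(seed, 4, n_seeds)
    out = {"gain": gain, "n_seeds": n_seeds}
    sign_ok, lag_ok, scores = [], [], []
    for true_lag in lags:
        s_list, l_list = [], []
        for sd in seeds:
            cfg = SynthConfig(duration=base.duration, n_trials=base.n_trials,
                              units=[UnitSpec(5.0, gain, true_lag)], seed=sd)
            _, _, _, (z,) = _session_zpairs(cfg)
            score, lag = sps.speed_score(sps.cross_correlogram(z))
            s_list.append(score)
            l_list.append(lag)
        sign_frac = float(np.mean(np.array(s_list) > 0))
        lag_frac = float(np.mean(np.abs(np.array(l_list) - true_lag) <= 0.2 + 1e-9))
        out[f"sign_frac_lag_{true_lag:+.1f}"] = sign_frac
        out[f"lag_frac_lag_{true_lag:+.1f}"] = lag_frac
        sign_ok.append(sign_frac)
        lag_ok.append(lag_frac)
        scores.extend(s_list)
    out["sign_frac_min"] = min(sign_ok)
    out["lag_frac_min"] = min(lag_ok)
    out["mean_recovered_score"] = float(np.mean(scores))
    return out


def bout_study(seed: int = 0) -> dict:
    """Bout detection and PSTH behavior on one 600-s positive-gain session.

    Reports event counts, the worst per-event deviation of the normalized
    PSTH bin-mean from 1, and the onset-aligned post/pre firing ratio of a
    positively speed-coupled unit.
    """
    cfg = SynthConfig(duration=600.0,
                      units=[UnitSpec(5.0, 0.25, 0.0)],
                      seed=_child_seeds(seed, 5, 1)[0])
    bundle, _ = generate_session(cfg)
    sp = kin.speed_from_track(bundle.position)
    rs = bts.resample_speed(sp)
    onsets = bts.detect_bouts(rs, "onset")
    offsets = bts.detect_bouts(rs, "offset")
    u = bundle.units[0]
    worst_norm = 0.0
    for ev in onsets + offsets:
        try:
            p1 = bts.event_psth(u, [ev])
        except Exception:
            continue
        worst_norm = max(worst_norm, abs(float(p1.norm_rate.mean()) - 1.0))
    p = bts.event_psth(u, onsets, speed=rs)
    return {"n_onsets": len(onsets), "n_offsets": len(offsets),
            "max_norm_mean_dev": worst_norm,
            "onset_post_pre_ratio": float(p.norm_rate[20:].mean()
                                          / p.norm_rate[:20].mean())}


def psth_onset_modulation_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of seeds where a positive-gain unit fires more after
    locomotion onset than before (onset-aligned PSTH)."""
    seeds = _child_seeds(seed, 6, n_seeds)
    hits = 0
    for sd in seeds:
        cfg = SynthConfig(duration=600.0, units=[UnitSpec(5.0, 0.25, 0.0)],
                          seed=sd)
        bundle, _ = generate_session(cfg)
        rs = bts.resample_speed(kin.speed_from_track(bundle.position))
        events = bts.detect_bouts(rs, "onset")
        if not events:
            continue
        p = bts.event_psth(bundle.units[0], events)
        hits += p.norm_rate[20:].mean() > p.norm_rate[:20].mean()
    return {"post_gt_pre_frac": hits / n_seeds, "n_seeds": n_seeds}


def decoding_sanity_study(n_seeds: int = 20, n_chance: int = 25,
                          seed: int = 0) -> dict:
    """Held-out R^2 for noiseless maps, uninformative units, and informative
    synthetic units against their own circular-shift chance level."""
    t = np.arange(300, dtype=float)
    rate = 3 + np.sin(2 * np.pi * t / 60) + 0.5 * np.sin(2 * np.pi * t / 37)
    seg = np.zeros(300, dtype=int)

    def prep(r, y):
        return dec.PreparedSeries(t, r, y, seg, rate_raw=r, speed_raw=y)

    linear = dec.decode_single(prep(rate, 2 + 3 * rate), "lin").r2
    cubic = dec.decode_single(
        prep(rate, 1 + 0.5 * rate + 0.2 * rate ** 3), "cub").r2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    null_r2 = float(np.mean([
        dec.decode_single(prep(rng.poisson(5, 300).astype(float),
                               2 + 3 * rate), "null").r2
        for _ in range(10)]))

    seeds = _child_seeds(seed, 8, n_seeds)
    beats = 0
    r2s, chances = [], []
    for sd in seeds:
        cfg = SynthConfig(duration=600.0, units=[UnitSpec(5.0, 0.25, 0.0)],
                          seed=sd)
        bundle, _ = generate_session(cfg)
        speed = kin.mask_epochs(kin.speed_from_track(bundle.position),
                                bundle.trials)
        p = dec.prepare_decoding_series(speed, bundle.units[0])
        res = dec.decode_single(p, "u")
        ch = dec.chance_level(p, "u", n_rep=n_chance,
                              rng=np.random.default_rng(sd + 1))
        beats += res.r2 > ch
        r2s.append(res.r2)
        chances.append(ch)
    return {"linear_r2": float(linear), "cubic_r2": float(cubic),
            "uninformative_r2": null_r2,
            "beats_chance_frac": beats / n_seeds,
            "informative_r2_mean": float(np.mean(r2s)),
            "chance_r2_mean": float(np.mean(chances)), "n_seeds": n_seeds}


def population_gain_study(n_units: int = 8, k_max: int = 5,
                          seed: int = 0) -> dict:
    """Multi-cell ridge decoding over all 1..k_max combinations of
    ``n_units`` informative units in one session.

    Returns mean R^2 per combination size and the one-sided Mann-Whitney p
    for each k -> k+1 increment.
    """
    cfg = SynthConfig(duration=600.0,
                      units=[UnitSpec(5.0, 0.25, 0.0) for _ in range(n_units)],
                      seed=_child_seeds(seed, 9, 1)[0])
    bundle, _ = generate_session(cfg)
    speed = kin.mask_epochs(kin.speed_from_track(bundle.position),
                            bundle.trials)
    preps = [dec.prepare_decoding_series(speed, u) for u in bundle.units]
    cols = np.column_stack([p.rate_raw for p in preps])
    df = dec.decode_multi(cols, preps[0].speed_raw, preps[0].seg_ids,
                          [u.unit_id for u in bundle.units], k_max=k_max,
                          seed=_child_seeds(seed, 10, 1)[0])
    out = {"n_combinations": int(len(df))}
    means = df.groupby("k")["r2"].mean()
    for k, m in means.items():
        out[f"mean_r2_k{k}"] = float(m)
    for k in range(1, k_max):
        a = df[df.k == k]["r2"]
        b = df[df.k == k + 1]["r2"]
        out[f"step_p_{k}_{k + 1}"] = float(
            stats.mannwhitneyu(a, b, alternative="less").pvalue)
    return out


def stability_study(n_seeds: int = 20, seed: int = 0) -> dict:
    """Subset-score constancy of a stationary speed cell.

    Per seed: one 900-s, 90-trial session with a single gain-calibrated unit;
    subset scores per block (5) and per cue/choice/outcome level; for each
    dimension a one-sample t-test of the subset scores against the session
    score. A seed passes when no dimension is significant at 0.05.
    """
    _, gain = recovery_conditions(seed)
    seeds = _child_seeds(seed, 11, n_seeds)
    passes = 0
    for sd in seeds:
        cfg = SynthConfig(duration=900.0, n_trials=90,
                          units=[UnitSpec(5.0, gain, 0.0)], seed=sd)
        bundle, _ = generate_session(cfg)
        trials = stab.assign_blocks(bundle.trials)
        blocked = SessionBundle(bundle.position, bundle.units, trials,
                                bundle.session_id)
        speed = kin.speed_from_track(bundle.position)
        df = stab.block_and_label_scores(blocked, bundle.units[0], speed=speed)
        full = df[df.dimension == "all"]["score"].iloc[0]
        ok = True
        for dim in ("block", "cue", "choice", "outcome"):
            vals = df[df.dimension == dim]["score"].dropna().to_numpy()
            if vals.size >= 2 and np.std(vals) > 0:
                ok &= stats.ttest_1samp(vals, full).pvalue > 0.05
        passes += ok
    return {"stable_seed_frac": passes / n_seeds, "n_seeds": n_seeds,
            "gain": gain}


def modulation_study(n_null_units: int = 200, n_power_seeds: int = 20,
                     n_shuffles: int = 1000, seed: int = 0) -> dict:
    """Calibration and power of the trial-label modulation test.

    Null: unmodulated 5-Hz units tested on all three label dimensions.
    Power: a +3 Hz rewarded-trial offset on a 5-Hz unit, 40 trials per
    session, detection fraction over seeds.
    """
    cfg = SynthConfig(duration=400.0, n_trials=40,
                      units=[UnitSpec(5.0, 0.0, 0.0)
                             for _ in range(n_null_units)],
                      seed=_child_seeds(seed, 12, 1)[0])
    bundle, _ = generate_session(cfg)
    flags = []
    streams = np.random.SeedSequence([seed, 13]).spawn(n_null_units)
    for u, ss in zip(bundle.units, streams):
        rng = np.random.default_rng(ss)
        for dim in ("cue", "choice", "outcome"):
            try:
                flags.append(stab.modulation_test(
                    u, bundle.trials, dim, n_shuffles=n_shuffles,
                    rng=rng).is_modulated)
            except AnalysisSkipped:
                pass
    null_frac = float(np.mean(flags))

    # a session can draw a state with < 2 trials and be untestable; such
    # seeds count as non-detections rather than aborting the study
    detected = 0
    for sd in _child_seeds(seed, 14, n_power_seeds):
        spec = UnitSpec(5.0, 0.0, 0.0,
                        label_modulation={"outcome": ("rewarded", 3.0)})
        cfg = SynthConfig(duration=400.0, n_trials=40, units=[spec], seed=sd)
        b, _ = generate_session(cfg)
        try:
            res = stab.modulation_test(b.units[0], b.trials, "outcome",
                                       n_shuffles=n_shuffles,
                                       rng=np.random.default_rng(sd + 1))
            detected += res.is_modulated
        except AnalysisSkipped:
            pass
    return {"null_flagged_frac": null_frac, "n_null_tests": len(flags),
            "power_frac": detected / n_power_seeds,
            "n_power_seeds": n_power_seeds}
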