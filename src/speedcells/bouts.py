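"""Locomotion-bout detection and event-aligned normalized PSTHs.

A locomotion *onset* is a time point where the preceding 2 s of speed are all
below 5 cm/s and at least 50% of the following 5 s are above it; an *offset*
is the mirror condition. Detection slides a 7-s window in 0.1-s steps over
the 0.1-s-resampled speed trace of each contiguous valid segment, accepting
the earliest qualifying window and resuming after it, so events of one kind
are at least 7 s apart and never straddle masked gaps.

Around each event, spiking is binned at 0.1 s from -2 to +5 s and normalized
by the event's own mean rate, so every retained event's normalized PSTH
averages exactly 1 across its 70 bins; events with zero spikes in the window
(normalization undefined) are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError
from .kinematics import SpeedSeries
from .dataio import SpikeTrain

DEFAULT_V_THRESH = 5.0  # cm/s
PRE_S = 2.0
POST_S = 5.0
BIN_S = 0.1
PRE_N = int(round(PRE_S / BIN_S))  # 20 samples
POST_N = int(round(POST_S / BIN_S))  # 50 samples
WIN_N = PRE_N + POST_N  # 70 samples


@dataclass
class BoutEvent:
    """One detected transition; ``t_ref`` is the boundary between the 2-s
    pre-window and the 5-s post-window (time 0 of the PSTH)."""

    kind: str  # "onset" | "offset"
    t_ref: float  # seconds


@dataclass
class PSTH:
    """Event-aligned, per-event-normalized firing rate with its speed trace."""

    bin_centers: np.ndarray  # seconds relative to t_ref, -2..+5
    norm_rate: np.ndarray  # unitless, mean across events
    sem: np.ndarray
    n_events: int
    n_excluded: int = 0  # zero-spike events dropped
    speed_mean: np.ndarray | None = None  # cm/s
    speed_sem: np.ndarray | None = None


def resample_speed(speed: SpeedSeries, bin_s: float = BIN_S):
    """Average the valid speed trace into ``bin_s`` bins per contiguous segment.

    Returns (times, values, seg_ids) arrays; bins anchored at each segment
    start, trailing partial bins dropped.
    """
    half = speed.dt / 2.0
    ts_all, vs_all, seg_all = [], [], []
    for seg_id, (i0, i1) in enumerate(speed.segments()):
        t_lo = speed.timestamps[i0] - half
        t_hi = speed.timestamps[i1 - 1] + half
        n_bins = int(np.floor((t_hi - t_lo) / bin_s + 1e-9))
        if n_bins < 1:
            continue
        ts = speed.timestamps[i0:i1]
        vs = speed.speed[i0:i1]
        starts = t_lo + bin_s * np.arange(n_bins)
        lo = np.searchsorted(ts, starts, side="left")
        hi = np.searchsorted(ts, starts + bin_s, side="left")
        cs = np.concatenate(([0.0], np.cumsum(vs)))
        counts = hi - lo
        keep = counts > 0
        ts_all.append((starts + bin_s / 2.0)[keep])
        vs_all.append(((cs[hi] - cs[lo]) / np.maximum(counts, 1))[keep])
        seg_all.append(np.full(int(keep.sum()), seg_id, dtype=int))
    if not ts_all:
        e = np.empty(0)
        return e, e.copy(), np.empty(0, dtype=int)
    return (np.concatenate(ts_all), np.concatenate(vs_all),
            np.concatenate(seg_all))


def detect_bouts(
    speed: SpeedSeries | tuple[np.ndarray, np.ndarray, np.ndarray],
    kind: str,
    v_thresh: float = DEFAULT_V_THRESH,
) -> list[BoutEvent]:
    """Detect locomotion onsets or offsets on the 0.1-s-resampled trace.

    Inequalities are strict: a sample exactly at ``v_thresh`` satisfies
    neither the low nor the high condition. Overlapping candidate windows
    resolve to the earliest; the scan then resumes after the accepted window.
    """
    if kind not in ("onset", "offset"):
        raise ValueError("kind must be 'onset' or 'offset'")
    if isinstance(speed, SpeedSeries):
        t, v, seg = resample_speed(speed)
    else:
        t, v, seg = speed
    events: list[BoutEvent] = []
    for s in np.unique(seg):
        m = seg == s
        events.extend(_detect_in_segment(t[m], v[m], kind, v_thresh))
    return events


def _detect_in_segment(t, v, kind, v_thresh) -> list[BoutEvent]:
    n = v.size
    if n < WIN_N:
        return []
    low = v < v_thresh
    high = v > v_thresh
    pre_ok, post_ok = (low, high) if kind == "onset" else (high, low)
    # prefix sums for O(1) window queries
    cpre = np.concatenate(([0], np.cumsum(pre_ok)))
    cpost = np.concatenate(([0], np.cumsum(post_ok)))
    need_post = POST_N // 2  # at least 50% of the 5-s window
    out = []
    i = 0
    while i <= n - WIN_N:
        all_pre = (cpre[i + PRE_N] - cpre[i]) == PRE_N
        enough_post = (cpost[i + WIN_N] - cpost[i + PRE_N]) >= need_post
        if all_pre and enough_post:
            # t_ref: edge between the last pre sample and the first post sample
            out.append(BoutEvent(kind, float(t[i + PRE_N] - BIN_S / 2.0)))
            i += WIN_N
        else:
            i += 1
    return out


def event_psth(
    unit: SpikeTrain,
    events: list[BoutEvent],
    bin_s: float = BIN_S,
    speed: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> PSTH:
    """Per-event-normalized PSTH (and mean speed trace) across events.

    Each event's firing rate in 0.1-s bins from -2 to +5 s is divided by that
    event's mean rate over the window, so its bin-mean is exactly 1. Events
    with zero spikes are excluded (normalization undefined) and counted in
    ``n_excluded``.
    """
    if not events:
        raise DegenerateSeriesError("event_psth needs at least one event")
    n_bins = int(round((PRE_S + POST_S) / bin_s))
    rel_edges = -PRE_S + bin_s * np.arange(n_bins + 1)
    centers = 0.5 * (rel_edges[:-1] + rel_edges[1:])
    kept_rows, speed_rows = [], []
    n_excluded = 0
    for ev in events:
        edges = ev.t_ref + rel_edges
        counts = np.diff(np.searchsorted(unit.spike_times, edges, side="left"))
        total = counts.sum()
        if total == 0:
            n_excluded += 1
            continue
        rate = counts / bin_s
        kept_rows.append(rate / (total / (PRE_S + POST_S)))
        if speed is not None:
            st, sv, _ = speed
            speed_rows.append(np.interp(ev.t_ref + centers, st, sv))
    if not kept_rows:
        raise DegenerateSeriesError("all events excluded (zero spikes in window)")
    R = np.vstack(kept_rows)
    n_ev = R.shape[0]
    sem = R.std(axis=0, ddof=1) / np.sqrt(n_ev) if n_ev > 1 else np.zeros(n_bins)
    sp_mean = sp_sem = None
    if speed_rows:
        S = np.vstack(speed_rows)
        sp_mean = S.mean(axis=0)
        sp_sem = S.std(axis=0, ddof=1) / np.sqrt(n_ev) if n_ev > 1 else np.zeros(n_bins)
    return PSTH(centers, R.mean(axis=0), sem, n_ev, n_excluded, sp_mean, sp_sem)


def psth_frame(unit_id: str, kind: str, p: PSTH) -> pd.DataFrame:
    """Long-format PSTH table (unit, kind, bin_center, norm_rate, sem, ...)."""
    df = pd.DataFrame({
        "unit_id": unit_id, "kind": kind, "bin_center": p.bin_centers,
        "norm_rate": p.norm_rate, "sem": p.sem, "n_events": p.n_events,
    })
    if p.speed_mean is not None:
        df["speed_mean"] = p.speed_mean
        df["speed_sem"] = p.speed_sem
    return df
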