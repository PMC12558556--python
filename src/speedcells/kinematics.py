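"""From raw tracks to the binned, z-scored speed / firing-rate series.

The preprocessing chain is: 5-point moving-average smoothing of X and Y,
instantaneous speed from successive displacements (cm/s), masking of samples
outside task epochs or with speed 0 (frozen tracking) or above 60 cm/s
(mistracking), then time-aligned binning of speed and per-unit firing rate
into overlapping 1-s windows advancing by 100 ms, and finally z-scoring so
that the peak of the cross-correlogram is a Pearson r.

Windows are anchored at the start of each contiguous run of valid samples and
never bridge two runs; each binned sample carries a segment id so downstream
lagged correlations only pair bins from the same contiguous stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import PositionTrack, SpikeTrain, TrialTable
from .errors import DegenerateSeriesError, ValidationError

DEFAULT_MAX_SPEED = 60.0  # cm/s, mistracking threshold
DEFAULT_BIN_S = 1.0
DEFAULT_OVERLAP_S = 0.9
DEFAULT_MIN_RATE = 0.5  # Hz, unit inclusion threshold


@dataclass
class SpeedSeries:
    """Instantaneous speed on the inter-sample midpoint grid, with validity mask."""

    timestamps: np.ndarray  # seconds, midpoints of position sample pairs
    speed: np.ndarray  # cm/s, >= 0
    valid_mask: np.ndarray  # bool, True where the sample enters the analysis
    dt: float  # sample spacing, seconds

    def __post_init__(self) -> None:
        if np.any(self.speed < 0):
            raise ValidationError("speed must be non-negative")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def segments(self) -> list[tuple[int, int]]:
        """Half-open index ranges [i0, i1) of contiguous valid samples."""
        m = self.valid_mask.astype(np.int8)
        d = np.diff(np.concatenate(([0], m, [0])))
        starts = np.nonzero(d == 1)[0]
        stops = np.nonzero(d == -1)[0]
        return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class BinnedPair:
    """Speed and one unit's firing rate on a common overlapping-window grid."""

    bin_centers: np.ndarray  # seconds
    speed_binned: np.ndarray  # cm/s, window mean of speed
    rate_binned: np.ndarray  # Hz, window spike count / bin_s
    seg_ids: np.ndarray  # int, contiguous-segment id per window
    bin_s: float = DEFAULT_BIN_S
    overlap_s: float = DEFAULT_OVERLAP_S

    @property
    def stride(self) -> float:
        return self.bin_s - self.overlap_s

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def is_empty(self) -> bool:
        return self.n_bins == 0


@dataclass
class ZScoredPair:
    """Z-scored speed / rate series on the :class:`BinnedPair` grid."""

    bin_centers: np.ndarray
    speed_z: np.ndarray
    rate_z: np.ndarray
    seg_ids: np.ndarray
    stride: float

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


def smooth_positions(track: PositionTrack) -> PositionTrack:
    """Centered 5-point moving average of x and y, length preserving.

    At the two samples on each end the window shrinks symmetrically is not
    possible, so a truncated (renormalized) window is used: no phase shift,
    no length change.
    """
    if track.n_samples < 5:
        raise ValidationError("5-point smoothing needs at least 5 samples")
    kernel = np.ones(5)
    norm = np.convolve(np.ones(track.n_samples), kernel, mode="same")
    xs = np.convolve(track.x, kernel, mode="same") / norm
    ys = np.convolve(track.y, kernel, mode="same") / norm
    return PositionTrack(track.timestamps, xs, ys, dt=track.dt)


def compute_speed(track: PositionTrack) -> SpeedSeries:
    """Instantaneous speed = displacement between successive samples / dt.

    Length n-1, timestamps at the midpoints of the sample pairs. All samples
    start out valid; apply :func:`mask_epochs` before binning.
    """
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    speed = np.hypot(dx, dy) / track.dt
    mid = 0.5 * (track.timestamps[:-1] + track.timestamps[1:])
    return SpeedSeries(mid, speed, np.ones(speed.size, dtype=bool), track.dt)


def speed_from_track(track: PositionTrack) -> SpeedSeries:
    """Convenience: smooth then differentiate."""
    return compute_speed(smooth_positions(track))


def mask_epochs(
    speed: SpeedSeries,
    trials: TrialTable,
    max_speed: float = DEFAULT_MAX_SPEED,
) -> SpeedSeries:
    """Keep samples inside some trial interval with 0 < speed <= max_speed.

    Speed exactly 0 (frozen tracking) and speed above ``max_speed``
    (mistracking) are excluded, as is everything outside task epochs.
    """
    if len(trials) == 0:
        raise ValidationError("cannot mask epochs with an empty trial table")
    # trial intervals are sorted and disjoint: sample t is in a trial iff the
    # latest trial starting at or before t has t_end > t
    idx = np.searchsorted(trials.t_start, speed.timestamps, side="right") - 1
    in_trial = idx >= 0
    in_trial[in_trial] &= speed.timestamps[in_trial] < trials.t_end[idx[in_trial]]
    ok = in_trial & (speed.speed > 0) & (speed.speed <= max_speed)
    return SpeedSeries(speed.timestamps, speed.speed, ok, speed.dt)


def bin_pair(
    speed: SpeedSeries,
    unit: SpikeTrain,
    bin_s: float = DEFAULT_BIN_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> BinnedPair:
    """Bin speed and firing rate into overlapping windows on a common grid.

    Windows of ``bin_s`` advance by ``stride = bin_s - overlap_s`` within each
    contiguous valid segment, anchored at the segment start; a window is kept
    only if it fits entirely inside the segment, so every kept window is built
    from valid samples only. Speed is the window mean; rate is the spike count
    in the half-open window divided by ``bin_s``.

    A session with no valid window yields an empty :class:`BinnedPair`
    (``is_empty``), not an exception.
    """
    if overlap_s >= bin_s:
        raise ValidationError("overlap_s must be smaller than bin_s")
    stride = bin_s - overlap_s
    half = speed.dt / 2.0
    centers, sp, rt, seg = [], [], [], []
    for seg_id, (i0, i1) in enumerate(speed.segments()):
        t_lo = speed.timestamps[i0] - half  # segment coverage start
        t_hi = speed.timestamps[i1 - 1] + half
        span = t_hi - t_lo
        n_win = int(np.floor((span - bin_s) / stride + 1e-9)) + 1
        if n_win <= 0:
            continue
        starts = t_lo + stride * np.arange(n_win)
        ends = starts + bin_s
        # mean speed of samples whose midpoint falls in [start, end)
        ts = speed.timestamps[i0:i1]
        vs = speed.speed[i0:i1]
        lo = np.searchsorted(ts, starts, side="left")
        hi = np.searchsorted(ts, ends, side="left")
        cs = np.concatenate(([0.0], np.cumsum(vs)))
        counts = hi - lo
        mean_v = (cs[hi] - cs[lo]) / np.maximum(counts, 1)
        # spike count in the half-open window
        s_lo = np.searchsorted(unit.spike_times, starts, side="left")
        s_hi = np.searchsorted(unit.spike_times, ends, side="left")
        keep = counts > 0
        centers.append((starts + bin_s / 2.0)[keep])
        sp.append(mean_v[keep])
        rt.append(((s_hi - s_lo) / bin_s)[keep])
        seg.append(np.full(int(keep.sum()), seg_id, dtype=int))
    if not centers:
        z = np.empty(0)
        return BinnedPair(z, z.copy(), z.copy(), np.empty(0, dtype=int), bin_s, overlap_s)
    return BinnedPair(
        np.concatenate(centers), np.concatenate(sp), np.concatenate(rt),
        np.concatenate(seg), bin_s, overlap_s,
    )


def zscore_pair(b: BinnedPair) -> ZScoredPair:
    """Z-score both series (population SD, n denominator).

    With the population SD the peak of the cross-correlogram of the z-scored
    series is exactly the Pearson correlation coefficient at that lag.
    """
    if b.is_empty:
        raise DegenerateSeriesError("cannot z-score an empty binned pair")
    out = []
    for name, x in (("speed", b.speed_binned), ("rate", b.rate_binned)):
        sd = float(np.std(x))
        if sd == 0.0:
            raise DegenerateSeriesError(f"zero-variance {name} series")
        out.append((x - np.mean(x)) / sd)
    return ZScoredPair(b.bin_centers, out[0], out[1], b.seg_ids, b.stride)


def unit_task_rate(unit: SpikeTrain, speed: SpeedSeries) -> float:
    """Mean firing rate over the valid task epochs (Hz).

    Spikes are attributed to the speed sample whose coverage interval
    (midpoint +/- dt/2) contains them; the denominator is the total valid time.
    """
    n_valid = speed.n_valid
    if n_valid == 0:
        return float("nan")
    half = speed.dt / 2.0
    edges = np.concatenate((speed.timestamps - half, [speed.timestamps[-1] + half]))
    idx = np.searchsorted(edges, unit.spike_times, side="right") - 1
    inside = (idx >= 0) & (idx < speed.timestamps.size)
    valid_spikes = int(np.sum(speed.valid_mask[idx[inside]]))
    return valid_spikes / (n_valid * speed.dt)


def filter_units(
    units: list[SpikeTrain],
    speed: SpeedSeries,
    min_rate: float = DEFAULT_MIN_RATE,
) -> tuple[list[SpikeTrain], list[tuple[str, float, str]]]:
    """Keep units with mean task-epoch firing rate strictly above ``min_rate``.

    Returns (included units, exclusion log) where each exclusion is
    (unit_id, rate_hz, reason).
    """
    kept, excluded = [], []
    for u in units:
        r = unit_task_rate(u, speed)
        if np.isnan(r):
            excluded.append((u.unit_id, r, "no valid task epochs"))
        elif r > min_rate:
            kept.append(u)
        else:
            excluded.append((u.unit_id, r, f"rate {r:.3f} Hz <= {min_rate} Hz"))
    return kept, excluded
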