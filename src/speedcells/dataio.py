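"""Session containers and plain-CSV persistence.

A recording session is a :class:`SessionBundle`: a uniformly sampled 2-D
position track, a list of spike trains with electrophysiological cell-type
labels (MSN / FSI / unknown), and a trial table carrying the four task labels
(cue, choice, outcome) plus a block index used by the stability analysis.

All times are session-relative seconds; intervals are half-open
``[t_start, t_end)`` so a spike at a trial boundary is counted exactly once.
Positions are centimeters (an optional ``pixels_per_cm`` converts raw pixel
tracks at read time). On disk every object is a delimited text table with a
one-line header, so fixtures stay diffable and language-neutral.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_DT = 0.0256  # position sampling period, seconds

CELL_TYPES = ("MSN", "FSI", "UNKNOWN")
CUE_LEVELS = ("visual", "spatial")
CHOICE_LEVELS = ("left", "right")
OUTCOME_LEVELS = ("rewarded", "non_rewarded")

#: label dimensions usable in stability / modulation analyses
LABEL_LEVELS = {"cue": CUE_LEVELS, "choice": CHOICE_LEVELS, "outcome": OUTCOME_LEVELS}

_TIME_TOL = 1e-6  # max deviation of a timestamp step from dt, seconds


@dataclass
class PositionTrack:
    """Uniformly sampled X/Y trajectory in centimeters."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.timestamps.size
        if not (self.x.size == self.y.size == n):
            raise ValidationError("timestamps, x and y must have equal length")
        if n < 6:
            raise ValidationError(
                f"position track needs >= 6 samples (got {n}): 5-point smoothing "
                "plus one displacement"
            )
        steps = np.diff(self.timestamps)
        if np.any(steps <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        worst = float(np.max(np.abs(steps - self.dt)))
        if worst > _TIME_TOL:
            raise ValidationError(
                f"non-uniform timestamps: max |step - dt| = {worst:.3g} s > {_TIME_TOL:g} s"
            )

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def t_start(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])


@dataclass
class SpikeTrain:
    """Spike times (seconds, sorted) for one unit with its cell-type label."""

    unit_id: str
    spike_times: np.ndarray
    cell_type: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.unit_id = str(self.unit_id)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"unit {self.unit_id}: cell_type {self.cell_type!r} not in {CELL_TYPES}"
            )

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class TrialTable:
    """Per-trial epochs and task labels.

    Intervals are half-open ``[t_start, t_end)``, sorted and pairwise disjoint.
    ``block`` is 0 for "not yet assigned"; :func:`speedcells.stability.assign_blocks`
    fills it with contiguous block indices 1..n_blocks.
    """

    trial_id: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    cue: np.ndarray
    choice: np.ndarray
    outcome: np.ndarray
    block: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.cue = np.asarray(self.cue, dtype=object)
        self.choice = np.asarray(self.choice, dtype=object)
        self.outcome = np.asarray(self.outcome, dtype=object)
        n = self.trial_id.size
        if self.block is None:
            self.block = np.zeros(n, dtype=int)
        else:
            self.block = np.asarray(self.block, dtype=int)
        for name in ("t_start", "t_end", "cue", "choice", "outcome", "block"):
            if getattr(self, name).size != n:
                raise ValidationError(f"trial table column {name!r} has wrong length")
        bad = np.nonzero(self.t_end <= self.t_start)[0]
        if bad.size:
            raise ValidationError(
                f"trial_id {int(self.trial_id[bad[0]])}: t_end <= t_start"
            )
        if n > 1:
            order = np.argsort(self.t_start, kind="stable")
            if not np.array_equal(order, np.arange(n)):
                raise ValidationError("trials must be sorted by t_start")
            overlap = np.nonzero(self.t_start[1:] < self.t_end[:-1])[0]
            if overlap.size:
                i = overlap[0]
                raise ValidationError(
                    f"trials {int(self.trial_id[i])} and {int(self.trial_id[i + 1])} overlap"
                )
        for name, levels in LABEL_LEVELS.items():
            col = getattr(self, name)
            for v in col:
                if v not in levels:
                    raise ValidationError(f"{name} label {v!r} not in {levels}")

    def __len__(self) -> int:
        return self.trial_id.size

    def select(self, mask: np.ndarray) -> "TrialTable":
        """Row-subset preserving order."""
        return TrialTable(
            self.trial_id[mask], self.t_start[mask], self.t_end[mask],
            self.cue[mask], self.choice[mask], self.outcome[mask], self.block[mask],
        )

    def labels(self, dimension: str) -> np.ndarray:
        if dimension == "block":
            return self.block
        if dimension not in LABEL_LEVELS:
            raise ValidationError(f"unknown trial dimension {dimension!r}")
        return getattr(self, dimension)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "t_start": self.t_start,
                "t_end": self.t_end,
                "cue": self.cue,
                "choice": self.choice,
                "outcome": self.outcome,
                "block": self.block,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        _require_columns(df, ("trial_id", "t_start", "t_end", "cue", "choice", "outcome"),
                         "trial table")
        block = df["block"].to_numpy() if "block" in df.columns else None
        for name in ("cue", "choice", "outcome"):
            if df[name].isna().any():
                raise ValidationError(f"trial table column {name!r} contains nulls")
        return cls(
            df["trial_id"].to_numpy(), df["t_start"].to_numpy(), df["t_end"].to_numpy(),
            df["cue"].to_numpy(dtype=object), df["choice"].to_numpy(dtype=object),
            df["outcome"].to_numpy(dtype=object), block,
        )


@dataclass
class SessionBundle:
    """One session: position track, spike trains, trial table."""

    position: PositionTrack
    units: list[SpikeTrain]
    trials: TrialTable
    session_id: str = "session"

    def __post_init__(self) -> None:
        t0, t1 = self.position.t_start, self.position.t_end
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < t0 - _TIME_TOL or
                               u.spike_times[-1] > t1 + _TIME_TOL):
                raise ValidationError(
                    f"unit {u.unit_id}: spikes outside position time range "
                    f"[{t0:.3f}, {t1:.3f}] s"
                )
        if len(self.trials):
            if self.trials.t_start[0] < t0 - _TIME_TOL or self.trials.t_end[-1] > t1 + _TIME_TOL:
                raise ValidationError("trial bounds outside position time range")

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == str(unit_id):
                return u
        raise KeyError(unit_id)


@dataclass
class ReaderConfig:
    """Options for :func:`read_session`."""

    dt: float = DEFAULT_DT
    pixels_per_cm: float | None = None  # convert raw pixel tracks to cm at read time
    session_id: str | None = None


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{what} is missing column {c!r}")


# ---------------------------------------------------------------------------
# session reading / writing

POSITION_FILE = "position.csv"
SPIKES_FILE = "spikes.csv"
TRIALS_FILE = "trials.csv"

def read_session(path: str, config: ReaderConfig | None = None) -> SessionBundle:
    """Read a session directory (position.csv, spikes.csv, trials.csv).

    ``position.csv`` has columns ``time,x,y``; ``spikes.csv`` is a long table
    ``unit_id,time,cell_type``; ``trials.csv`` carries
    ``trial_id,t_start,t_end,cue,choice,outcome[,block]``.
    """
    config = config or ReaderConfig()
    pos_path = os.path.join(path, POSITION_FILE)
    if not os.path.exists(pos_path):
        raise FormatError(f"no {POSITION_FILE} in {path}")
    pos = pd.read_csv(pos_path)
    _require_columns(pos, ("time", "x", "y"), POSITION_FILE)
    scale = 1.0 / config.pixels_per_cm if config.pixels_per_cm else 1.0
    track = PositionTrack(
        pos["time"].to_numpy(), pos["x"].to_numpy() * scale,
        pos["y"].to_numpy() * scale, dt=config.dt,
    )

    spk = pd.read_csv(os.path.join(path, SPIKES_FILE))
    _require_columns(spk, ("unit_id", "time", "cell_type"), SPIKES_FILE)
    units = []
    for uid, grp in spk.groupby("unit_id", sort=True):
        ct = grp["cell_type"].iloc[0]
        units.append(SpikeTrain(str(uid), np.sort(grp["time"].to_numpy()), str(ct)))

    trials = TrialTable.from_frame(pd.read_csv(os.path.join(path, TRIALS_FILE)))
    session_id = config.session_id or os.path.basename(os.path.normpath(path))
    bundle = SessionBundle(track, units, trials, session_id)
    log.info(
        "read session %s: %d units, %.1f s, %d trials",
        session_id, len(units), track.t_end - track.t_start, len(trials),
    )
    return bundle


def write_session(bundle: SessionBundle, path: str) -> None:
    """Write a session as the three-CSV layout read by :func:`read_session`."""
    os.makedirs(path, exist_ok=True)
    pd.DataFrame(
        {"time": bundle.position.timestamps, "x": bundle.position.x, "y": bundle.position.y}
    ).to_csv(os.path.join(path, POSITION_FILE), index=False)
    rows = []
    for u in bundle.units:
        rows.append(pd.DataFrame(
            {"unit_id": u.unit_id, "time": u.spike_times, "cell_type": u.cell_type}
        ))
    spk = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "time", "cell_type"])
    spk.to_csv(os.path.join(path, SPIKES_FILE), index=False)
    bundle.trials.to_frame().to_csv(
        os.path.join(path, TRIALS_FILE), index=False)


def write_results(results: dict[str, pd.DataFrame] | pd.DataFrame, path: str) -> None:
    """Write one tidy CSV per result family.

    ``results`` maps a family name (``speed_scores``, ``stability``, ``bouts``,
    ``decoding``...) to a flat table; a bare DataFrame is written to ``path``
    directly. NaNs (e.g. the undefined lag of a degenerate unit) survive the
    round-trip as empty fields.
    """
    if isinstance(results, pd.DataFrame):
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        results.to_csv(path, index=False)
        return
    os.makedirs(path, exist_ok=True)
    for name, df in results.items():
        df.to_csv(os.path.join(path, f"{name}.csv"), index=False)


def read_results(path: str) -> dict[str, pd.DataFrame]:
    """Read back every CSV table under ``path`` keyed by file stem."""
    out = {}
    for fn in sorted(os.listdir(path)):
        if fn.endswith(".csv"):
            out[fn[:-4]] = pd.read_csv(os.path.join(path, fn))
    return out


# ---------------------------------------------------------------------------
# flat key-value configuration files

def read_config(path: str) -> dict[str, object]:
    """Parse a flat ``key=value`` config file (e.g. ``speed.bin_s=1.0``).

    Values are coerced to int, then float, then bool, else kept as strings.
    Blank lines and ``#`` comments are ignored.
    """
    out: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            key, _, raw = line.partition("=")
            out[key.strip()] = _coerce(raw.strip())
    return out


def _coerce(raw: str) -> object:
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw.lower() in ("true", "false"):
        return raw.lower() == "true"
    return raw
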