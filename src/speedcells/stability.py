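"""Speed-score stability across trial subsets and label-modulation tests.

Two questions: (1) does a unit's speed score change with elapsed time
(contiguous trial blocks), cue type, spatial choice, or trial outcome?
Subset scores reuse the exact full-session scoring machinery restricted to
bins inside the subset's trials. (2) Is a unit's mean firing rate itself
modulated by a task label? Tested with a trial-label permutation null and
the same +/-2 SD rule used for speed-cell classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import LABEL_LEVELS, SessionBundle, SpikeTrain, TrialTable
from .errors import AnalysisSkipped, DegenerateSeriesError, ValidationError
from . import kinematics as kin
from . import speedscore as sps

DEFAULT_N_BLOCKS = 5
DEFAULT_MIN_PER_BLOCK = 11
DEFAULT_N_SHUFFLES = 10_000


@dataclass
class SubsetSpec:
    """One trial subset: a dimension (block/cue/choice/outcome) and a level."""

    dimension: str
    level: object

    def __post_init__(self) -> None:
        if self.dimension == "block":
            return
        levels = LABEL_LEVELS.get(self.dimension)
        if levels is None:
            raise ValidationError(f"unknown dimension {self.dimension!r}")
        if self.level not in levels:
            raise ValidationError(
                f"level {self.level!r} not valid for dimension {self.dimension!r}")


@dataclass
class ModulationResult:
    """Firing-rate difference between two trial states vs its shuffle null."""

    unit_id: str
    dimension: str
    delta_rate: float  # Hz, state A mean - state B mean
    surrogate_mean: float
    surrogate_sd: float
    is_modulated: bool


def assign_blocks(
    trials: TrialTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    min_per_block: int = DEFAULT_MIN_PER_BLOCK,
) -> TrialTable:
    """Assign contiguous, near-equal trial blocks in temporal order.

    Remainder trials go to the earliest blocks (59 trials -> 12,12,12,12,11).
    If the session cannot fill ``n_blocks`` of ``min_per_block`` trials, fewer
    blocks are used with a warning; below two feasible blocks the stability
    analysis is skipped.
    """
    n = len(trials)
    nb = min(n_blocks, n // min_per_block)
    if nb < 2:
        raise AnalysisSkipped(
            f"{n} trials cannot form 2 blocks of >= {min_per_block}")
    if nb < n_blocks:
        warnings.warn(
            f"only {n} trials: using {nb} blocks instead of {n_blocks}",
            stacklevel=2)
    base, rem = divmod(n, nb)
    sizes = [base + 1] * rem + [base] * (nb - rem)
    block = np.repeat(np.arange(1, nb + 1), sizes)
    return TrialTable(trials.trial_id, trials.t_start, trials.t_end,
                      trials.cue, trials.choice, trials.outcome, block)


def subset_speed_score(
    bundle: SessionBundle,
    unit: SpikeTrain,
    spec: SubsetSpec | None,
    bin_s: float = kin.DEFAULT_BIN_S,
    overlap_s: float = kin.DEFAULT_OVERLAP_S,
    max_speed: float = kin.DEFAULT_MAX_SPEED,
    max_lag_s: float = sps.DEFAULT_MAX_LAG_S,
    speed: kin.SpeedSeries | None = None,
) -> dict:
    """Speed score computed exactly as for the full session, restricted to
    one trial subset (``spec=None`` means all trials).

    Returns a dict with score, lag_s, n_bins; score/lag are NaN (with a
    reason) when the subset has too few valid bins.
    """
    if speed is None:
        speed = kin.speed_from_track(bundle.position)
    trials = bundle.trials
    if spec is not None:
        mask = trials.labels(spec.dimension) == spec.level
        trials = trials.select(mask)
    out = {"unit_id": unit.unit_id,
           "dimension": spec.dimension if spec else "all",
           "level": spec.level if spec else "all",
           "score": float("nan"), "lag_s": float("nan"), "n_bins": 0,
           "reason": ""}
    if len(trials) == 0:
        out["reason"] = "subset contains no trials"
        return out
    masked = kin.mask_epochs(speed, trials, max_speed)
    try:
        z = kin.zscore_pair(kin.bin_pair(masked, unit, bin_s, overlap_s))
        out["n_bins"] = z.n_bins
        score, lag = sps.speed_score(sps.cross_correlogram(z, max_lag_s))
    except DegenerateSeriesError as exc:
        out["reason"] = str(exc)
        return out
    out["score"], out["lag_s"] = score, lag
    return out


def block_and_label_scores(
    bundle: SessionBundle,
    unit: SpikeTrain,
    **kwargs,
) -> pd.DataFrame:
    """Subset scores for every block and both levels of cue/choice/outcome,
    plus the full-session reference row (dimension 'all')."""
    trials = bundle.trials
    rows = [subset_speed_score(bundle, unit, None, **kwargs)]
    for b in sorted(set(trials.block.tolist())):
        if b > 0:
            rows.append(subset_speed_score(
                bundle, unit, SubsetSpec("block", int(b)), **kwargs))
    for dim, levels in LABEL_LEVELS.items():
        for lv in levels:
            rows.append(subset_speed_score(
                bundle, unit, SubsetSpec(dim, lv), **kwargs))
    return pd.DataFrame(rows)


def per_trial_rates(unit: SpikeTrain, trials: TrialTable) -> np.ndarray:
    """In-trial spike count / trial duration, Hz, per trial."""
    lo = np.searchsorted(unit.spike_times, trials.t_start, side="left")
    hi = np.searchsorted(unit.spike_times, trials.t_end, side="left")
    return (hi - lo) / (trials.t_end - trials.t_start)


def modulation_test(
    unit: SpikeTrain,
    trials: TrialTable,
    dimension: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ModulationResult:
    """Is this unit's mean per-trial firing rate modulated by a task label?

    delta = mean rate in state A - mean rate in state B, compared to a null
    from whole-trial label permutations (state counts preserved); modulated
    iff |delta - null mean| > 2 * null SD.
    """
    if dimension not in LABEL_LEVELS:
        raise ValidationError(f"dimension must be one of {list(LABEL_LEVELS)}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    level_a, level_b = LABEL_LEVELS[dimension]
    labels = trials.labels(dimension)
    rates = per_trial_rates(unit, trials)
    in_a = labels == level_a
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if min(n_a, n_b) < 2:
        raise AnalysisSkipped(
            f"dimension {dimension!r}: a state has fewer than 2 trials")
    delta = float(rates[in_a].mean() - rates[~in_a].mean())
    # permuting which trials count as state A == permuting the rate vector
    n = rates.size
    idx = np.argsort(rng.random((n_shuffles, n)), axis=1)[:, :n_a]
    picked = rates[idx]
    sum_a = picked.sum(axis=1)
    total = rates.sum()
    deltas = sum_a / n_a - (total - sum_a) / n_b
    mu, sd = float(deltas.mean()), float(deltas.std())
    return ModulationResult(
        unit_id=unit.unit_id, dimension=dimension, delta_rate=delta,
        surrogate_mean=mu, surrogate_sd=sd,
        is_modulated=bool(abs(delta - mu) > 2.0 * sd),
    )


def modulation_frame(results: list[ModulationResult]) -> pd.DataFrame:
    cols = ["unit_id", "dimension", "delta_rate", "surrogate_mean",
            "surrogate_sd", "is_modulated"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
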