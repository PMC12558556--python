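"""Speed score, speed lag, circular-shift surrogate null, and speed-cell calls.

The speed score of a unit is the signed peak (maximum absolute value,
carrying its sign) of the cross-correlogram between the z-scored firing-rate
and speed series; the lag of that peak is the speed lag, with positive lags
meaning rate changes *follow* speed changes. Significance comes from a
surrogate null built by circularly rotating the rate series by a random 20-50%
of the analyzed time and recomputing the score; a unit is a speed cell when
its score exceeds +/-2 surrogate SDs from the surrogate mean and its
Benjamini-Hochberg adjusted empirical p-value is below alpha.

Lagged correlations only pair bins belonging to the same contiguous segment
of the analyzed series: shifting across a gap between task epochs would
fabricate spurious alignments. The surrogate rotation, in contrast, operates
on the concatenated sequence of analyzed bins, which is the "total analyzed
time" the shift percentages refer to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSeriesError, ValidationError
from .kinematics import ZScoredPair

DEFAULT_MAX_LAG_S = 5.0
DEFAULT_N_SURROGATES = 10_000
DEFAULT_SHIFT_FRAC = (0.2, 0.5)
DEFAULT_ALPHA = 0.05
N_MIN_PAIRS = 30  # Pearson r is unstable below this many pairs

STRENGTH_WEAK_MAX = 0.2
STRENGTH_MODERATE_MAX = 0.4


@dataclass
class CCG:
    """Cross-correlogram: Pearson r per lag, with pair counts.

    Lags are a symmetric grid at the bin stride; ``r`` is NaN at lags with
    fewer than ``n_min`` same-segment pairs.
    """

    lags: np.ndarray  # seconds
    r: np.ndarray  # Pearson r per lag, NaN where undefined
    n_pairs: np.ndarray  # pairs contributing per lag


@dataclass
class SpeedScoreResult:
    """Score, lag and significance bookkeeping for one unit."""

    unit_id: str
    cell_type: str
    score: float
    lag_s: float
    surrogate_mean: float
    surrogate_sd: float
    p_emp: float
    p_fdr: float = float("nan")
    is_speed_cell: bool = False
    sign: str = ""
    strength: str = ""
    exceeds_2sd: bool = False


# ---------------------------------------------------------------------------
# vectorized lagged-correlation engine

def _lag_design(speed_z: np.ndarray, seg_ids: np.ndarray, lags: np.ndarray):
    """Precompute the per-lag masked speed design shared by all rate rows.

    For lag k (in strides), rate bin j is paired with speed bin j-k when both
    exist and share a segment id. Returns (Y, M, stats) where Y[j, i] is the
    paired speed value (0 where invalid), M[j, i] the validity indicator for
    lag lags[i], and stats the per-lag (n, sum_y, sum_y2).
    """
    L = speed_z.size
    K = lags.size
    Y = np.zeros((L, K))
    M = np.zeros((L, K))
    n = np.zeros(K)
    sum_y = np.zeros(K)
    sum_y2 = np.zeros(K)
    for i, k in enumerate(lags):
        k = int(k)
        if abs(k) >= L:
            continue
        if k >= 0:
            valid = seg_ids[k:] == seg_ids[: L - k]
            Y[k:, i][valid] = speed_z[: L - k][valid]
            M[k:, i][valid] = 1.0
        else:
            m = -k
            valid = seg_ids[: L - m] == seg_ids[m:]
            Y[: L - m, i][valid] = speed_z[m:][valid]
            M[: L - m, i][valid] = 1.0
        n[i] = valid.sum()
        col = Y[:, i]
        sum_y[i] = col.sum()
        sum_y2[i] = (col * col).sum()
    return Y, M, (n, sum_y, sum_y2)


def _ccg_rows(rate_rows: np.ndarray, design, n_min: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r at every lag for each row of ``rate_rows`` (shape (m, L)).

    Uses the shared design from :func:`_lag_design`; returns (r (m, K), n (K,)).
    """
    Y, M, (n, sum_y, sum_y2) = design
    S_xy = rate_rows @ Y
    S_x = rate_rows @ M
    S_x2 = (rate_rows * rate_rows) @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.where(n > 0, n, 1.0)
        cov = S_xy - S_x * (sum_y / n_safe)
        var_x = S_x2 - S_x * S_x / n_safe
        var_y = sum_y2 - sum_y * sum_y / n_safe
        r = cov / np.sqrt(var_x * var_y)
    r[:, n < n_min] = np.nan
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r, n.astype(int)


def _lag_grid(stride: float, max_lag_s: float) -> np.ndarray:
    k_max = int(np.floor(max_lag_s / stride + 1e-9))
    return np.arange(-k_max, k_max + 1)


def cross_correlogram(
    z: ZScoredPair,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    n_min: int = N_MIN_PAIRS,
) -> CCG:
    """Pearson correlation between rate and speed at every lag on the stride grid.

    Positive lag delays the rate series relative to speed: r at lag k pairs
    rate bin j with speed bin j-k (rate follows speed when the peak is at
    positive lag).
    """
    lags_k = _lag_grid(z.stride, max_lag_s)
    design = _lag_design(z.speed_z, z.seg_ids, lags_k)
    r, n = _ccg_rows(z.rate_z[None, :], design, n_min)
    r = r[0]
    if np.all(np.isnan(r)):
        raise DegenerateSeriesError(
            f"fewer than {n_min} same-segment pairs at every lag"
        )
    return CCG(lags_k * z.stride, r, n)


def _peak_index(r: np.ndarray, lags: np.ndarray) -> int:
    """Index of max |r|; ties broken toward the lag closest to 0, then the
    more negative lag."""
    absr = np.abs(r)
    order = np.lexsort((lags, np.abs(lags), -absr))
    for idx in order:
        if np.isfinite(absr[idx]):
            return int(idx)
    raise DegenerateSeriesError("cross-correlogram has no finite lag")


def speed_score(ccg: CCG) -> tuple[float, float]:
    """(score, lag_s): the signed value and lag of the absolute CCG peak.

    Negative scores are genuine peaks (units whose rate falls as the animal
    speeds up), so the peak is taken in absolute value and reported signed.
    """
    i = _peak_index(ccg.r, ccg.lags)
    return float(ccg.r[i]), float(ccg.lags[i])


def surrogate_null(
    z: ZScoredPair,
    n_surr: int = DEFAULT_N_SURROGATES,
    shift_frac: tuple[float, float] = DEFAULT_SHIFT_FRAC,
    seed: int | None = None,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    n_min: int = N_MIN_PAIRS,
    rng: np.random.Generator | None = None,
    _design=None,
) -> np.ndarray:
    """Surrogate speed scores from random circular shifts of the rate series.

    Each surrogate rotates the concatenated analyzed rate series by a shift
    drawn uniformly from ``shift_frac`` of its length, in a random direction,
    and recomputes the full speed score (peak of |r| over the same lag grid).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = z.n_bins
    lags_k = _lag_grid(z.stride, max_lag_s)
    s_min = int(np.ceil(shift_frac[0] * L))
    s_max = int(np.floor(shift_frac[1] * L))
    if s_max < s_min or s_min < 1:
        raise ValidationError(
            f"series of {L} bins too short for circular shifts in "
            f"[{shift_frac[0]:.0%}, {shift_frac[1]:.0%}] of its length"
        )
    if s_min < lags_k.max():
        raise ValidationError(
            "minimum circular shift is shorter than the lag search window; "
            "surrogates would overlap the true alignment"
        )
    design = _design if _design is not None else _lag_design(z.speed_z, z.seg_ids, lags_k)
    shifts = rng.integers(s_min, s_max + 1, size=n_surr)
    signs = rng.choice(np.array([-1, 1]), size=n_surr)
    scores = np.empty(n_surr)
    chunk = max(1, int(2e7) // max(L, 1))  # bound the rotated-matrix memory
    base = np.arange(L)
    for c0 in range(0, n_surr, chunk):
        c1 = min(c0 + chunk, n_surr)
        idx = (base[None, :] - (signs[c0:c1] * shifts[c0:c1])[:, None]) % L
        rows = z.rate_z[idx]
        r, _ = _ccg_rows(rows, design, n_min)
        absr = np.where(np.isnan(r), -np.inf, np.abs(r))
        peak = np.argmax(absr, axis=1)
        scores[c0:c1] = r[np.arange(c1 - c0), peak]
    return scores


def classify_unit(
    unit_id: str,
    score: float,
    lag_s: float,
    surrogates: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    cell_type: str = "UNKNOWN",
) -> SpeedScoreResult:
    """Pre-FDR classification fields for one unit.

    The score is selected as the largest-magnitude CCG value, so its
    surrogate null is the distribution of the surrogate peak *magnitude*
    with an arbitrary sign: the +/-2 SD band is therefore applied to the
    magnitude null (a score in either tail -- strongly positive or strongly
    negative -- exceeds it), which keeps the rule's false-positive rate near
    the nominal two-sided level. ``surrogate_mean``/``surrogate_sd`` store
    the magnitude-null statistics; ``p_emp`` is the add-one empirical
    p-value of the score's magnitude under that null. The final
    ``is_speed_cell`` flag is set by :func:`finalize_classification` after
    BH adjustment across units.
    """
    surrogates = np.asarray(surrogates, dtype=float)
    n = surrogates.size
    mags = np.abs(surrogates - np.mean(surrogates))
    mu = float(np.mean(mags))
    sd = float(np.std(mags))
    if sd == 0.0:
        raise DegenerateSeriesError(f"unit {unit_id}: zero surrogate SD")
    dev = abs(score - float(np.mean(surrogates)))
    p_emp = (1.0 + np.sum(mags >= dev)) / (n + 1.0)
    return SpeedScoreResult(
        unit_id=str(unit_id),
        cell_type=cell_type,
        score=float(score),
        lag_s=float(lag_s),
        surrogate_mean=mu,
        surrogate_sd=sd,
        p_emp=float(p_emp),
        exceeds_2sd=bool(dev > mu + 2.0 * sd),
        sign="positive" if score > 0 else "negative",
        strength=strength_class(score),
    )


def fdr_adjust(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def strength_class(score: float) -> str:
    """Weak (|r| < 0.2), moderate (0.2 to 0.4), strong (|r| > 0.4)."""
    a = abs(score)
    if a < STRENGTH_WEAK_MAX:
        return "weak"
    if a <= STRENGTH_MODERATE_MAX:
        return "moderate"
    return "strong"


def finalize_classification(
    results: list[SpeedScoreResult], alpha: float = DEFAULT_ALPHA
) -> list[SpeedScoreResult]:
    """BH-adjust empirical p-values across units and set ``is_speed_cell``.

    A unit is a speed cell iff it passes the +/-2 surrogate-SD rule *and* its
    BH-adjusted empirical p-value is below ``alpha``.
    """
    if not results:
        return results
    adj = fdr_adjust(np.array([r.p_emp for r in results]), alpha)
    for res, pa in zip(results, adj):
        res.p_fdr = float(pa)
        res.is_speed_cell = bool(res.exceeds_2sd and pa < alpha)
    return results


def score_session(
    bundle,
    n_surr: int = DEFAULT_N_SURROGATES,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    bin_s: float | None = None,
    overlap_s: float | None = None,
    max_speed: float | None = None,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    min_rate: float | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Full per-session speed-score pipeline.

    Smooths the track, masks invalid epochs, drops units at or below the
    inclusion rate, computes each unit's score/lag and surrogate null, then
    BH-adjusts across units. Returns the result table and an exclusion log of
    (unit_id, reason) for degenerate or low-rate units.
    """
    from . import kinematics as kin

    bin_s = kin.DEFAULT_BIN_S if bin_s is None else bin_s
    overlap_s = kin.DEFAULT_OVERLAP_S if overlap_s is None else overlap_s
    max_speed = kin.DEFAULT_MAX_SPEED if max_speed is None else max_speed
    min_rate = kin.DEFAULT_MIN_RATE if min_rate is None else min_rate

    speed = kin.mask_epochs(kin.speed_from_track(bundle.position), bundle.trials, max_speed)
    units, excluded = kin.filter_units(bundle.units, speed, min_rate)
    exclusions = [(uid, reason) for uid, _, reason in excluded]

    results: list[SpeedScoreResult] = []
    design = None
    lags_k = None
    seeds = np.random.SeedSequence(seed).spawn(len(units))
    for u, ss in zip(units, seeds):
        try:
            z = kin.zscore_pair(kin.bin_pair(speed, u, bin_s, overlap_s))
            if design is None:
                lags_k = _lag_grid(z.stride, max_lag_s)
                design = _lag_design(z.speed_z, z.seg_ids, lags_k)
            r, n_pairs = _ccg_rows(z.rate_z[None, :], design, N_MIN_PAIRS)
            ccg = CCG(lags_k * z.stride, r[0], n_pairs)
            sc, lag = speed_score(ccg)
            surr = surrogate_null(
                z, n_surr=n_surr, rng=np.random.default_rng(ss),
                max_lag_s=max_lag_s, _design=design,
            )
            results.append(classify_unit(u.unit_id, sc, lag, surr,
                                         alpha=alpha, cell_type=u.cell_type))
        except DegenerateSeriesError as exc:
            exclusions.append((u.unit_id, str(exc)))
    finalize_classification(results, alpha)
    return results_frame(results), exclusions


def results_frame(results: list[SpeedScoreResult]) -> pd.DataFrame:
    cols = ["unit_id", "cell_type", "score", "lag_s", "surrogate_mean",
            "surrogate_sd", "p_emp", "p_fdr", "is_speed_cell", "sign",
            "strength", "exceeds_2sd"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)
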