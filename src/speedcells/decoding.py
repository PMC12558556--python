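"""Decoding locomotion speed from firing rates.

Single units: rate and speed are binned into disjoint 1-s bins, upper-capped
at the 95th percentile (Winsorized), smoothed with a Gaussian kernel
(SD = 1 bin), expanded into degree-3 polynomial features and fit with
ordinary least squares under 10-fold cross-validation on contiguous,
unshuffled temporal folds. Decoding accuracy is the mean held-out R^2 (which
can be negative). Chance levels repeat the identical pipeline on circularly
shifted rate series (shift uniform in 20-50% of the analyzed length,
100 repetitions).

Multi-unit: all 1-5 cell combinations of units with single-cell R^2 >= 0.1,
each contributing its own degree-3 polynomial features (no cross-unit
interaction terms), fit with ridge regression (alpha = 1) on standardized
features. Combination surrogates rotate every member series by one common
shift per repetition, preserving inter-unit structure.

To avoid train/test leakage, Winsorization caps and feature standardization
are fit on the training folds only and applied to the held-out fold; the
Gaussian smoothing (a short, symmetric, label-free filter) follows the
published whole-series application.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score

from .errors import AnalysisSkipped, ValidationError
from .kinematics import SpeedSeries, bin_pair
from .dataio import SpikeTrain

DEFAULT_DEGREE = 3
DEFAULT_N_FOLDS = 10
DEFAULT_WINSOR_PCT = 95.0
DEFAULT_SMOOTH_SD = 1.0  # bins (= seconds at 1-s bins)
DEFAULT_N_CHANCE = 100
DEFAULT_SHIFT_FRAC = (0.2, 0.5)
DEFAULT_R2_GATE = 0.1
DEFAULT_RIDGE_ALPHA = 1.0
MIN_BINS = 30


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy for one unit or combination."""

    unit_ids: tuple[str, ...]
    r2: float  # mean over folds; NaN for degenerate designs
    fold_r2: np.ndarray
    chance_r2: float = float("nan")
    n_folds: int = DEFAULT_N_FOLDS
    reason: str = ""


def winsorize_upper(x: np.ndarray, pct: float = DEFAULT_WINSOR_PCT,
                    cap: float | None = None) -> np.ndarray:
    """Cap values above the series' own ``pct`` percentile (linear-interpolation
    percentile); the lower tail is untouched. Idempotent."""
    if cap is None:
        cap = float(np.percentile(x, pct))
    return np.minimum(x, cap)


def gaussian_smooth(
    x: np.ndarray, seg_ids: np.ndarray | None = None,
    sd_bins: float = DEFAULT_SMOOTH_SD, truncate: float = 4.0,
) -> np.ndarray:
    """Gaussian smoothing per contiguous segment, kernel truncated at
    ``truncate`` SDs and renormalized at segment edges (no spill across gaps,
    constant series are fixed points)."""
    half = int(np.ceil(truncate * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    out = np.empty_like(x, dtype=float)
    if seg_ids is None:
        seg_ids = np.zeros(x.size, dtype=int)
    lo = k.size // 2  # center slice of the full convolution, any segment length
    for s in np.unique(seg_ids):
        m = seg_ids == s
        xs = x[m]
        norm = np.convolve(np.ones(xs.size), k, mode="full")[lo:lo + xs.size]
        out[m] = np.convolve(xs, k, mode="full")[lo:lo + xs.size] / norm
    return out


@dataclass
class PreparedSeries:
    """Aligned disjoint-1-s-bin feature/target series for decoding."""

    bin_centers: np.ndarray
    rate: np.ndarray  # Hz, Winsorized + smoothed
    speed: np.ndarray  # cm/s, Winsorized + smoothed
    seg_ids: np.ndarray
    rate_raw: np.ndarray = field(repr=False, default=None)
    speed_raw: np.ndarray = field(repr=False, default=None)


def prepare_decoding_series(
    speed: SpeedSeries,
    unit: SpikeTrain,
    bin_s: float = 1.0,
    winsor_pct: float = DEFAULT_WINSOR_PCT,
    smooth_sd: float = DEFAULT_SMOOTH_SD,
) -> PreparedSeries:
    """Disjoint 1-s binning, upper Winsorization, Gaussian smoothing.

    The returned ``rate``/``speed`` are the descriptive whole-series
    transforms; ``rate_raw``/``speed_raw`` keep the untransformed bins that
    the cross-validated decoders re-process with training-fold-only caps.
    """
    b = bin_pair(speed, unit, bin_s=bin_s, overlap_s=0.0)
    if b.n_bins < MIN_BINS:
        raise AnalysisSkipped(
            f"decoding needs >= {MIN_BINS} valid 1-s bins, got {b.n_bins}")
    rate = gaussian_smooth(winsorize_upper(b.rate_binned, winsor_pct),
                           b.seg_ids, smooth_sd)
    spd = gaussian_smooth(winsorize_upper(b.speed_binned, winsor_pct),
                          b.seg_ids, smooth_sd)
    return PreparedSeries(b.bin_centers, rate, spd, b.seg_ids,
                          rate_raw=b.rate_binned, speed_raw=b.speed_binned)


def contiguous_folds(n: int, n_folds: int = DEFAULT_N_FOLDS) -> list[np.ndarray]:
    """Disjoint contiguous index blocks covering 0..n-1, sizes differing <= 1."""
    return [a for a in np.array_split(np.arange(n), n_folds) if a.size]


def _cv_r2(
    rate_cols: np.ndarray,  # (n_bins, n_units) raw binned rates
    speed_raw: np.ndarray,
    seg_ids: np.ndarray,
    degree: int,
    n_folds: int,
    winsor_pct: float,
    smooth_sd: float,
    model: str,
    ridge_alpha: float,
) -> np.ndarray:
    """Per-fold held-out R^2 with training-fold-fit caps and standardization."""
    n = speed_raw.size
    folds = contiguous_folds(n, n_folds)
    fold_r2 = np.empty(len(folds))
    for fi, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test, assume_unique=True)
        # caps fit on training bins only
        X_c = np.column_stack([
            winsorize_upper(rate_cols[:, j],
                            cap=float(np.percentile(rate_cols[train, j], winsor_pct)))
            for j in range(rate_cols.shape[1])
        ])
        y_c = winsorize_upper(speed_raw,
                              cap=float(np.percentile(speed_raw[train], winsor_pct)))
        X_s = np.column_stack([gaussian_smooth(X_c[:, j], seg_ids, smooth_sd)
                               for j in range(X_c.shape[1])])
        y_s = gaussian_smooth(y_c, seg_ids, smooth_sd)
        # per-unit polynomial features, no cross-unit interactions
        feats = np.column_stack([X_s ** d for d in range(1, degree + 1)])
        if model == "ols":
            reg = LinearRegression()
            Xtr, Xte = feats[train], feats[test]
        else:
            mu = feats[train].mean(axis=0)
            sd = feats[train].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (feats[train] - mu) / sd
            Xte = (feats[test] - mu) / sd
            reg = Ridge(alpha=ridge_alpha)
        reg.fit(Xtr, y_s[train])
        fold_r2[fi] = r2_score(y_s[test], reg.predict(Xte))
    return fold_r2


def decode_single(
    prepared: PreparedSeries,
    unit_id: str = "unit",
    degree: int = DEFAULT_DEGREE,
    n_folds: int = DEFAULT_N_FOLDS,
    winsor_pct: float = DEFAULT_WINSOR_PCT,
    smooth_sd: float = DEFAULT_SMOOTH_SD,
) -> DecodingResult:
    """Polynomial (degree-3) OLS decoding of speed from one unit's rate,
    10-fold contiguous cross-validation."""
    if np.std(prepared.rate_raw) == 0:
        return DecodingResult((unit_id,), float("nan"), np.full(n_folds, np.nan),
                              n_folds=n_folds, reason="constant rate (singular design)")
    fold_r2 = _cv_r2(prepared.rate_raw[:, None], prepared.speed_raw,
                     prepared.seg_ids, degree, n_folds, winsor_pct, smooth_sd,
                     "ols", 0.0)
    return DecodingResult((unit_id,), float(fold_r2.mean()), fold_r2,
                          n_folds=n_folds)


def chance_level(
    prepared: PreparedSeries,
    unit_id: str = "unit",
    n_rep: int = DEFAULT_N_CHANCE,
    shift_frac: tuple[float, float] = DEFAULT_SHIFT_FRAC,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    **decode_kwargs,
) -> float:
    """Mean decoding R^2 over circular-shift surrogates of the rate series."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = prepared.speed_raw.size
    s_min = max(1, int(np.ceil(shift_frac[0] * n)))
    s_max = int(np.floor(shift_frac[1] * n))
    if s_max < s_min:
        raise ValidationError("series too short for the chance-level shifts")
    vals = np.empty(n_rep)
    for i in range(n_rep):
        shift = int(rng.integers(s_min, s_max + 1)) * int(rng.choice((-1, 1)))
        rolled = PreparedSeries(
            prepared.bin_centers, prepared.rate, prepared.speed,
            prepared.seg_ids, rate_raw=np.roll(prepared.rate_raw, shift),
            speed_raw=prepared.speed_raw)
        vals[i] = decode_single(rolled, unit_id, **decode_kwargs).r2
    return float(np.nanmean(vals))


def decode_multi(
    rate_cols: np.ndarray,  # (n_bins, n_units) raw disjoint-bin rates
    speed_raw: np.ndarray,
    seg_ids: np.ndarray,
    unit_ids: list[str],
    k_max: int = 5,
    r2_gate: float = DEFAULT_R2_GATE,
    ridge_alpha: float = DEFAULT_RIDGE_ALPHA,
    degree: int = DEFAULT_DEGREE,
    n_folds: int = DEFAULT_N_FOLDS,
    winsor_pct: float = DEFAULT_WINSOR_PCT,
    smooth_sd: float = DEFAULT_SMOOTH_SD,
    n_chance: int = 0,
    shift_frac: tuple[float, float] = DEFAULT_SHIFT_FRAC,
    seed: int | None = None,
    single_r2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ridge decoding over all 1..k_max combinations of eligible units.

    Eligibility is single-cell OLS R^2 >= ``r2_gate`` (computed here unless
    ``single_r2`` is supplied). With ``n_chance > 0``, each combination also
    gets a surrogate mean R^2 from common circular shifts applied to all its
    members simultaneously. Returns a tidy table (unit_ids, k, r2, chance_r2).
    """
    n_units = rate_cols.shape[1]
    if single_r2 is None:
        single_r2 = np.array([
            decode_single(
                PreparedSeries(None, None, None, seg_ids,
                               rate_raw=rate_cols[:, j], speed_raw=speed_raw),
                unit_ids[j], degree, n_folds, winsor_pct, smooth_sd).r2
            for j in range(n_units)
        ])
    eligible = [j for j in range(n_units)
                if np.isfinite(single_r2[j]) and single_r2[j] >= r2_gate]
    if not eligible:
        raise AnalysisSkipped(f"no unit reaches single-cell R^2 >= {r2_gate}")
    rng = np.random.default_rng(seed)
    n = speed_raw.size
    s_min = max(1, int(np.ceil(shift_frac[0] * n)))
    s_max = int(np.floor(shift_frac[1] * n))
    rows = []
    for k in range(1, min(k_max, len(eligible)) + 1):
        for combo in itertools.combinations(eligible, k):
            cols = rate_cols[:, combo]
            fold_r2 = _cv_r2(cols, speed_raw, seg_ids, degree, n_folds,
                             winsor_pct, smooth_sd, "ridge", ridge_alpha)
            chance = float("nan")
            if n_chance > 0:
                ch = np.empty(n_chance)
                for i in range(n_chance):
                    shift = int(rng.integers(s_min, s_max + 1)) * int(rng.choice((-1, 1)))
                    ch[i] = _cv_r2(np.roll(cols, shift, axis=0), speed_raw,
                                   seg_ids, degree, n_folds, winsor_pct,
                                   smooth_sd, "ridge", ridge_alpha).mean()
                chance = float(ch.mean())
            rows.append({
                "unit_ids": "+".join(unit_ids[j] for j in combo),
                "k": k, "r2": float(fold_r2.mean()), "chance_r2": chance,
            })
    return pd.DataFrame(rows)
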