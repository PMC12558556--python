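"""Population summaries, group-level statistics, and pipeline orchestration.

The summaries mirror the structure of the study's result tables: counts and
fractions of speed cells overall and split by cell type and correlation sign,
score/lag means with SEM, and the weak/moderate/strong breakdown. Group
comparisons delegate to standard statistical routines (t-tests, Mann-Whitney,
Wilcoxon, repeated-measures ANOVA) with Bonferroni or BH correction.

``run_all`` chains synth -> kinematics -> speed scores -> stability -> bouts
-> decoding -> summaries, writes one tidy CSV per result family plus a run
manifest (config snapshot, seed, package version, per-file content hashes);
an identical manifest implies bit-identical stochastic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from . import bouts as bts
from . import decoding as dec
from . import kinematics as kin
from . import speedscore as sps
from . import stability as stab
from . import synth
from .dataio import SessionBundle, read_session, write_results, write_session
from .errors import AnalysisSkipped, DegenerateSeriesError, SpeedcellsError

log = logging.getLogger(__name__)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def summarize_population(scores: pd.DataFrame) -> pd.DataFrame:
    """Speed-cell counts/fractions and score/lag statistics per group.

    One row per group (all units, each cell type, each sign among speed
    cells, each strength class among speed cells). Empty groups yield n = 0
    with NaN statistics rather than failing.
    """
    if scores.empty:
        raise SpeedcellsError("summarize_population needs a non-empty score table")

    def row(name: str, df: pd.DataFrame) -> dict:
        n = len(df)
        n_sc = int(df["is_speed_cell"].sum()) if n else 0
        sub = df[df["is_speed_cell"]] if n else df
        return {
            "group": name, "n": n, "n_speed_cells": n_sc,
            "fraction_speed_cells": n_sc / n if n else float("nan"),
            "score_mean": float(sub["score"].mean()) if len(sub) else float("nan"),
            "score_sem": _sem(sub["score"].to_numpy()) if len(sub) else float("nan"),
            "lag_mean": float(sub["lag_s"].mean()) if len(sub) else float("nan"),
            "lag_sem": _sem(sub["lag_s"].to_numpy()) if len(sub) else float("nan"),
        }

    rows = [row("all", scores)]
    for ct in ("MSN", "FSI", "UNKNOWN"):
        g = scores[scores["cell_type"] == ct]
        if len(g):
            rows.append(row(f"cell_type={ct}", g))
    sc = scores[scores["is_speed_cell"]]
    for sign in ("positive", "negative"):
        rows.append(row(f"speed_cells:sign={sign}", sc[sc["sign"] == sign]))
    for strength in ("weak", "moderate", "strong"):
        rows.append(row(f"speed_cells:strength={strength}",
                        sc[sc["strength"] == strength]))
    return pd.DataFrame(rows)


_TESTS = {
    "unpaired_t": lambda a, b: stats.ttest_ind(a, b),
    "paired_t": lambda a, b: stats.ttest_rel(a, b),
    "one_sample_t": lambda a, mu: stats.ttest_1samp(a, mu),
    "mannwhitney": lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided"),
    "wilcoxon": lambda a, b: stats.wilcoxon(a, b),
}


def group_tests(
    comparisons: list[dict], correction: str = "bonferroni",
) -> pd.DataFrame:
    """Run a batch of standard two-group / one-sample tests.

    Each comparison is a dict with ``name``, ``kind`` (one of unpaired_t,
    paired_t, one_sample_t, mannwhitney, wilcoxon), ``a`` and ``b`` (``b`` is
    the null mean for one_sample_t). Groups with n < 2 are skipped with a
    reason. ``correction`` is 'bonferroni' (p_adj = min(1, m*p)) or 'fdr_bh'.
    """
    rows = []
    for comp in comparisons:
        kind = comp["kind"]
        a = np.asarray(comp["a"], dtype=float)
        b = comp.get("b", 0.0)
        name = comp.get("name", kind)
        if kind not in _TESTS:
            raise SpeedcellsError(f"unknown test kind {kind!r}")
        b_arr = np.atleast_1d(np.asarray(b, dtype=float))
        too_small = a.size < 2 or (kind != "one_sample_t" and b_arr.size < 2)
        if too_small:
            rows.append({"name": name, "kind": kind, "n_a": a.size,
                         "n_b": b_arr.size, "direction": np.nan,
                         "statistic": np.nan, "p": np.nan,
                         "skipped": "group with n < 2"})
            continue
        arg_b = float(b_arr[0]) if kind == "one_sample_t" else b_arr
        res = _TESTS[kind](a, arg_b)
        direction = float(np.sign(a.mean() - (arg_b if kind == "one_sample_t"
                                              else b_arr.mean())))
        rows.append({"name": name, "kind": kind, "n_a": a.size,
                     "n_b": b_arr.size, "direction": direction,
                     "statistic": float(res.statistic), "p": float(res.pvalue),
                     "skipped": ""})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    m = int(ok.sum())
    df["p_adj"] = np.nan
    if m:
        if correction == "bonferroni":
            df.loc[ok, "p_adj"] = np.minimum(1.0, df.loc[ok, "p"] * m)
        elif correction == "fdr_bh":
            df.loc[ok, "p_adj"] = sps.fdr_adjust(df.loc[ok, "p"].to_numpy())
        else:
            raise SpeedcellsError(f"unknown correction {correction!r}")
    return df


# ---------------------------------------------------------------------------
# orchestration

ALL_STAGES = ("score", "stability", "bouts", "decode", "summary")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    out_dir: str,
    session_dir: str | None = None,
    synth_config: synth.SynthConfig | None = None,
    seed: int = 0,
    n_surrogates: int = sps.DEFAULT_N_SURROGATES,
    n_shuffles: int = stab.DEFAULT_N_SHUFFLES,
    n_chance: int = dec.DEFAULT_N_CHANCE,
    k_max: int = 5,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the full pipeline on a session directory or a synthetic config.

    Writes one CSV per result family under ``out_dir`` plus ``manifest.json``
    and returns the manifest. Any stage failure aborts with the stage name.
    """
    if (session_dir is None) == (synth_config is None):
        raise SpeedcellsError("provide exactly one of session_dir / synth_config")
    os.makedirs(out_dir, exist_ok=True)
    if synth_config is not None:
        bundle, _truth = synth.generate_session(synth_config)
        write_session(bundle, os.path.join(out_dir, "session"))
    else:
        if not os.path.isdir(session_dir):
            raise SpeedcellsError(f"session path does not exist: {session_dir}")
        bundle = read_session(session_dir)

    results: dict[str, pd.DataFrame] = {}
    stage = "score"
    try:
        scores, exclusions = sps.score_session(
            bundle, n_surr=n_surrogates, seed=seed)
        results["speed_scores"] = scores
        results["excluded_units"] = pd.DataFrame(
            exclusions, columns=["unit_id", "reason"])

        if "stability" in stages:
            stage = "stability"
            results["stability"], results["modulation"] = _stability_stage(
                bundle, scores, seed, n_shuffles)
        if "bouts" in stages:
            stage = "bouts"
            results["bout_psth"], results["bout_events"] = _bouts_stage(bundle)
        if "decode" in stages:
            stage = "decode"
            results["decoding_single"], results["decoding_multi"] = _decode_stage(
                bundle, seed, n_chance, k_max)
        if "summary" in stages:
            stage = "summary"
            results["population_summary"] = summarize_population(scores)
    except SpeedcellsError as exc:
        raise SpeedcellsError(f"stage {stage!r} failed: {exc}") from exc

    write_results(results, out_dir)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "session_id": bundle.session_id,
        "config": {
            "n_surrogates": n_surrogates, "n_shuffles": n_shuffles,
            "n_chance": n_chance, "k_max": k_max, "stages": list(stages),
            "synth": dataclasses.asdict(synth_config) if synth_config else None,
        },
        "outputs": {f"{name}.csv": _hash_file(os.path.join(out_dir, f"{name}.csv"))
                    for name in sorted(results)},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stability_stage(bundle, scores, seed, n_shuffles):
    try:
        trials = stab.assign_blocks(bundle.trials)
    except AnalysisSkipped as exc:
        log.warning("stability skipped: %s", exc)
        return pd.DataFrame(), pd.DataFrame()
    blocked = SessionBundle(bundle.position, bundle.units, trials,
                            bundle.session_id)
    speed = kin.speed_from_track(bundle.position)
    sub_rows, mod_results = [], []
    seeds = np.random.SeedSequence((seed, 1)).spawn(len(bundle.units))
    scored = set(scores["unit_id"].astype(str))
    for u, ss in zip(bundle.units, seeds):
        if u.unit_id not in scored:
            continue
        sub_rows.append(stab.block_and_label_scores(blocked, u, speed=speed))
        for dim in ("cue", "choice", "outcome"):
            try:
                mod_results.append(stab.modulation_test(
                    u, trials, dim, n_shuffles=n_shuffles,
                    rng=np.random.default_rng(ss)))
            except AnalysisSkipped as exc:
                log.warning("modulation test skipped (%s): %s", u.unit_id, exc)
    subsets = pd.concat(sub_rows, ignore_index=True) if sub_rows else pd.DataFrame()
    return subsets, stab.modulation_frame(mod_results)


def _bouts_stage(bundle):
    # bouts are not confined to trial epochs (a 7-s window rarely fits inside
    # one trial), so detection runs on the whole-session trace with only the
    # artifact samples (speed 0 or > 60 cm/s) masked out
    sp = kin.speed_from_track(bundle.position)
    speed = kin.SpeedSeries(
        sp.timestamps, sp.speed,
        (sp.speed > 0) & (sp.speed <= kin.DEFAULT_MAX_SPEED), sp.dt)
    rs = bts.resample_speed(speed)
    psth_rows, ev_rows = [], []
    for kind in ("onset", "offset"):
        events = bts.detect_bouts(rs, kind)
        ev_rows.extend({"kind": kind, "t_ref": e.t_ref} for e in events)
        if not events:
            continue
        for u in bundle.units:
            try:
                p = bts.event_psth(u, events, speed=rs)
            except DegenerateSeriesError:
                continue
            psth_rows.append(bts.psth_frame(u.unit_id, kind, p))
    psth = pd.concat(psth_rows, ignore_index=True) if psth_rows else pd.DataFrame()
    return psth, pd.DataFrame(ev_rows, columns=["kind", "t_ref"])


def _decode_stage(bundle, seed, n_chance, k_max):
    speed = kin.mask_epochs(kin.speed_from_track(bundle.position), bundle.trials)
    singles, prepared = [], {}
    seeds = np.random.SeedSequence((seed, 2)).spawn(len(bundle.units) + 1)
    for u, ss in zip(bundle.units, seeds):
        try:
            prep = dec.prepare_decoding_series(speed, u)
        except AnalysisSkipped as exc:
            log.warning("decoding skipped (%s): %s", u.unit_id, exc)
            continue
        res = dec.decode_single(prep, u.unit_id)
        if n_chance > 0 and np.isfinite(res.r2):
            res.chance_r2 = dec.chance_level(
                prep, u.unit_id, n_rep=n_chance, rng=np.random.default_rng(ss))
        prepared[u.unit_id] = prep
        singles.append({"unit_id": u.unit_id, "r2": res.r2,
                        "chance_r2": res.chance_r2, "reason": res.reason})
    single_df = pd.DataFrame(singles)
    multi_df = pd.DataFrame()
    if prepared:
        ids = list(prepared)
        rate_cols = np.column_stack([prepared[i].rate_raw for i in ids])
        any_prep = prepared[ids[0]]
        try:
            multi_df = dec.decode_multi(
                rate_cols, any_prep.speed_raw, any_prep.seg_ids, ids,
                k_max=k_max, seed=int(seeds[-1].generate_state(1)[0] % (2**31)),
                single_r2=single_df["r2"].to_numpy())
        except AnalysisSkipped as exc:
            log.warning("multi-cell decoding skipped: %s", exc)
    return single_df, multi_df
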