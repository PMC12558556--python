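# Methods

This note documents the models, estimators and numerical choices behind
`speedcells`, the conditions under which the validation studies run, and what
passing them does and does not establish.

## Kinematics

Position is sampled uniformly (default period 0.0256 s) in centimeters; an
optional `pixels_per_cm` converts raw pixel tracks at read time (tracking
calibration must come from the user — it cannot be inferred from the data).
X and Y are smoothed with a centered 5-point moving average (edge windows
truncated and renormalized: length-preserving, no phase shift). Instantaneous
speed is the Euclidean displacement between successive smoothed samples
divided by the sampling period, placed on the midpoint grid (length n−1).

Samples are masked out when they fall outside task epochs (trial intervals,
half-open `[t_start, t_end)`), when speed is exactly 0 (frozen tracking), or
above 60 cm/s (mistracking). Speed and per-unit firing rate are then binned
into 1-s windows advancing by 0.1 s (900-ms overlap), anchored at the start
of each contiguous run of valid samples; windows never bridge two runs, and
any window that would touch an invalid sample is dropped from *both* series,
keeping them on one grid. Rate is window spike count / 1 s; with overlap 0
the binning exactly conserves spike counts over the covered windows.
Z-scoring uses the population (n-denominator) SD so the cross-correlogram
peak is exactly a Pearson r. Units whose mean rate over valid task epochs is
not strictly above 0.5 Hz are excluded up front (the inclusion rate is
computed over task epochs; whole-recording rates would differ only for
units active mainly between trials).

## Speed score, lag, and the surrogate null

The cross-correlogram evaluates, for every lag on the 0.1-s stride grid
within ±5 s, the Pearson correlation between the rate series delayed by that
lag and the speed series, using only bin pairs from the same contiguous
segment (shifting across a gap would fabricate alignments). Lags need at
least 30 contributing pairs. The ±5-s window comfortably covers the lags
reported for striatal units (roughly −2.4 to +2.2 s). The **speed score** is
the value at the lag maximizing |r|, carrying its sign — negative scores are
genuine peaks for negatively coupled units. Ties break toward the lag
nearest 0, then the more negative lag.

Surrogates rotate the concatenated analyzed rate series circularly by a
uniform 20–50% of its length (both directions) and recompute the full score;
rotation preserves the rate autocorrelation while destroying the alignment
with speed. The minimum shift must exceed the lag window, otherwise
surrogates would overlap the true alignment.

**Choice of significance band.** Because the score is *selected* as the
largest-|r| value, its null distribution is the surrogate peak-magnitude
distribution with an arbitrary sign — symmetric and bimodal, with an SD
comparable to the typical peak magnitude itself. A ±2 SD band computed on
the signed surrogate scores is therefore essentially unreachable (measured
false-positive rate ~0% on speed-independent units), while the same band
computed on the magnitude null (score deviation from the signed surrogate
mean compared against mean + 2 SD of the surrogate deviations) operates near
the intended two-sided level: 3–7% pre-FDR across seeds, against the ~4.6%
a Gaussian two-sided 2-SD rule targets. The package uses the magnitude-null
band; `surrogate_mean`/`surrogate_sd` store the magnitude-null statistics,
and the empirical p-value is the add-one rank of the score's deviation in
that null. A unit is a speed cell iff it passes the band *and* its
BH-adjusted empirical p is below α = 0.05 (both gates are stored, so either
can be reported alone). Strength classes are |score| < 0.2 (weak), 0.2–0.4
(moderate), > 0.4 (strong).

## Stability and label modulation

Trial blocks are contiguous in time, near-equal, remainder to the earliest
blocks (59 trials → 12,12,12,12,11); fewer blocks are used (with a warning)
when five blocks of ≥ 11 trials do not fit, and the analysis is skipped below
two feasible blocks. Subset speed scores rerun the identical scoring pipeline
restricted to one subset's trials; a subset equal to the full session
reproduces the session score bit-for-bit. Short subsets occasionally report
their peak with flipped sign: the stop/run alternation gives the CCG
oscillatory sidelobes, and in a noisy subset a sidelobe can edge past the
true peak. Constancy statements about subsets are therefore most robust on
peak magnitudes.

The modulation test uses per-trial rates (in-trial spike count / trial
duration, raw spikes, no binning — the question is about trial-level means),
takes the difference of state means, and compares it to a null from
whole-trial label permutations (state counts preserved; default 10,000
shuffles, 1,000 in the scaled-down studies). The ±2 SD rule is applied to
this null directly — the permutation distribution of a mean difference is
unimodal and approximately Gaussian, so no magnitude correction is needed
(measured null rate 3–5%). States with fewer than 2 trials are untestable
and reported as skipped.

## Locomotion bouts and PSTHs

Bout detection runs on the speed trace averaged into 0.1-s bins per
contiguous valid segment. An onset requires all samples in a 2-s pre-window
strictly below 5 cm/s and at least 50% of the following 5-s window strictly
above it; offsets mirror the rule; samples exactly at threshold satisfy
neither. The 7-s window slides in 0.1-s steps; the earliest qualifying
window is accepted and the scan resumes after it, so same-kind events are
≥ 7 s apart. Two consequences worth knowing: the event time `t_ref` (the
pre/post boundary) can precede the actual threshold crossing by up to 2.5 s,
because the 50% persistence tolerates sub-threshold time at the start of the
post-window; and events never straddle masked gaps, since detection is
per-segment. In the pipeline, bout detection runs on the whole-session trace
with only artifact samples masked — locomotion bouts are not confined to
trial epochs, and a 7-s window rarely fits inside a single trial.

PSTHs bin spikes at 0.1 s from −2 to +5 s around `t_ref` and divide each
event's rate by that event's mean rate over the window, so every retained
event's normalized bins average exactly 1; events with zero spikes in the
window are excluded (normalization undefined) and counted. Flatness of a
constant-rate unit's PSTH is judged by the count of bins outside ±3 SEM
(at most the chance-expected number), not by demanding zero: with 70 bins a
truly flat PSTH exceeds a per-bin 3-SEM band about one run in six by
multiplicity alone.

## Decoding

Rate and speed are binned into disjoint 1-s bins (overlapping bins would
leak across contiguous CV folds), upper-capped at their own 95th percentile
(linear-interpolation percentile; "capping" reads as upper-tail only), and
smoothed with a Gaussian kernel (SD 1 bin, truncated at ±4 SD, renormalized
at segment edges). Cross-validation uses 10 contiguous, unshuffled temporal
folds (sizes differing by ≤ 1). To keep the held-out fold untouched by its
own statistics, Winsorization caps and (for ridge) feature standardization
are fit on the training folds only and applied to the test fold; the
smoothing, a short symmetric label-free filter, follows the published
whole-series application. Single units use {x, x², x³} features with OLS;
accuracy is the mean held-out R² (negative when worse than the mean
predictor). Chance levels rerun the identical pipeline on circularly shifted
rate series (20–50% of the length, 100 repetitions by default, fewer in the
scaled studies). Multi-unit models take all 1–5-cell combinations of units
with single-cell R² ≥ 0.1, each contributing its own degree-3 features (no
cross-unit interaction terms, which the per-cell feature description
implies), standardized, under ridge with α = 1; combination surrogates apply
one common rotation to all member series per repetition, preserving
inter-unit structure ("simultaneous" shifts; independent per-unit shifts are
available via the single-unit path).

## The synthetic generator

`synth` builds sessions from known ground truth. Speed is a semi-Markov
alternation of stop (OU process around 1 cm/s, floored at 0) and run
(OU around 20 cm/s) states with gamma-distributed durations (shape 4; means
3 s and 5 s), integrated into a 2-D track through a smoothed random heading;
recomputed speed matches the generated truth to < 5% RMS of the mean
(smoothing attenuation only). Tracking artifacts (frozen position → speed
exactly 0; 2.5-cm jumps → speed > 60 cm/s) are injected at a configurable
rate (default 0.5/min). Trials tile the session with 0.5-s gaps; cue
alternates in 10-trial blocks, choice is uniform, reward probability 0.75.

Spike trains are inhomogeneous Poisson with intensity
`softplus(baseline + gain · speed(t − lag) + label offsets)`, drawn by exact
thinning on a 1-ms grid. The softplus link keeps intensities positive by
construction while effectively linear at working rates; the linearity of
real rate–speed relations is an empirical finding, not something the
generator should hard-code. `calibrate_gain` refines the analytic gain
(which ignores smoothing/binning attenuation) by probe simulation so studies
can state their conditions as a *realized* correlation. Ground truth (unit
parameters, true speed, transition times, artifact times) is returned as a
separate object never passed to analysis code.

What the generator does not emulate: maze geometry and genuinely
trial-locked kinematics (speed bouts are independent of trial boundaries),
waveform features behind the MSN/FSI labels, theta-band or bursty spike-time
structure, and multiplexed coding (position, acceleration). Passing the
validation studies therefore shows the estimators are correct and calibrated
under Poisson firing with known speed coupling — not that every conclusion
transfers to recordings with richer temporal structure.

## Validation-study conditions

Chosen once as part of the study design: oracle equivalence on 50 random
gapless AR(1) pairs of 300–2000 strides; null calibration on 200
speed-independent 5-Hz units over two independent 600-s sessions (two
sessions de-correlate units, which share a speed trace within a session)
with 1,000 surrogates per unit; parameter recovery on 900-s, 90-trial
single-unit sessions, 20 seeds per injected lag ∈ {−0.5, 0, +0.5} s, gain
calibrated to a realized r ≈ 0.4; stability on the same session template,
judging each label dimension by a one-sample t-test of its subset scores
against the session score; decoding sanity on 300-bin analytic series plus
20 seeded 600-s sessions with 25-shift chance levels; the population-gain
study on one 600-s session with 8 informative units (218 combinations);
modulation calibration on 200 unmodulated units × 3 dimensions and power on
a +3 Hz rewarded-trial offset, 40-trial sessions, 20 seeds. These sizes keep
the full validation run in the low minutes on one CPU while leaving each
assertion's sampling error well inside its margin.

## Known limitations

- Lag estimates discretize to the 0.1-s stride; sub-stride couplings are
  rounded.
- The CCG's oscillatory sidelobes (from rhythmic stop/run behavior) can
  dominate short-subset peaks; prefer magnitude comparisons for subsets
  under ~1000 bins.
- The 2-SD band on the peak-magnitude null is calibrated only approximately
  (3–7% across seeds); the empirical p-value with BH adjustment is the
  better-behaved gate and both are stored.
- `unit_task_rate` attributes spikes to speed samples by nearest coverage
  interval; spikes in masked gaps shorter than one sample period are
  counted toward the neighboring sample.
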