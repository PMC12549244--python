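# Methods

`physiotrust` re-creates, as tested software, an analysis pipeline that
infers an operator's trust in an autonomous system from multimodal
physiological signals, task-interaction ("embedded") measures and operator
background information. Because the human-subject data behind such studies
is typically not deposited, the package pairs the analysis chain with a
synthetic study generator that plants known structure, so every stage can
be validated against ground truth.

## The study the generator emulates

The emulated protocol is a human-on-the-loop supervision task: an operator
monitors a simulated autonomous system classifying satellite imagery over
**12 participants x 4 sessions x 6 trials x 8 epochs of 45 s** (2,304
epochs). At the end of every epoch the operator reports trust on a
continuous [0, 1] slider; that report is the regression target `y`. Each
session pairs the operator with one cell of a 2x2 condition grid — system
reliability (67% vs 84% correct) crossed with explainability (terse vs
naturalistic communication). Each session opens with a 2-minute resting
pre-experimental baseline; trials 2-6 are preceded by 45-s pre-trial
baselines, and trial 1's pre-trial baseline is taken to be the last 45 s of
the pre-experimental period (trial 1 starts immediately after it).

## Synthetic data model

### Planted trust structure

Trust is generated as

    y = clip(b0 + delta_p + c_s + sum_i beta_i z_i + eps, 0, 1)

with intercept `b0 = 0.55`, a per-participant dispositional offset
`delta_p ~ N(0, 0.05)`, a session-condition shift `c_s` (+-0.05 for
reliability, +-0.02 for explainability), reporting noise
`eps ~ N(0, 0.06)`, and 15 latent epoch states `z_i ~ N(0, 1)` that are
realized physically in the raw signals (below). The planted coefficients
share one magnitude chosen so the latent signal explains 85% of the
unclipped trust variance; with 15 predictors this gives |beta| ~ 0.037,
i.e. each effect is ~0.62 residual standard deviations — comfortably above
the 0.3-SD floor the recovery tests assume. (An alternative reading of
"effects >= 0.3 SD" — 0.3 SD of `y` each — is arithmetically impossible at
a total signal share of 85% with 15 predictors, since 15 x 0.3^2 > 1; the
residual-SD convention is therefore used.)

The 15 planted features span all six streams: mean heart rate and RR-interval
SD (ECG); tonic skin conductance level and mean SCR amplitude (EDA); breath
rate and respiration amplitude (RSP); Pz alpha power, Fz theta power and
occipital beta power (EEG); channel-3 and channel-7 HbO activation (fNIRS);
pupil diameter, fixation duration, saccade amplitude and blink duration
(eye). Each latent `z_i` shifts the corresponding generator parameter, e.g.
mean HR = 72 + 6 z bpm, tonic SCL = 8 + 1.5 z µS, Pz alpha target power
x (1 + 0.35 z).

Several extracted features are deterministic near-duplicates of a planted
parameter's primary readout (mean RR vs mean HR; RMSSD = sqrt(2) SDNN for
i.i.d. RR intervals; tonic mean vs raw SCL mean). LASSO keeps an arbitrary
member of such a group, so the ground-truth object records a documented
**alias group** per planted feature, and support recovery counts any
version of any alias. This is the honest notion of recovery under exact
proxy collinearity.

### Signal physics

* **ECG** — template P-QRS-T complexes at RR intervals drawn i.i.d.
  Normal(60/HR, hrv_sd); optional 60-Hz mains contamination; 500 Hz.
* **EDA** — slow tonic drift plus Bateman-kernel SCRs (rise tau 0.75 s,
  decay tau 2 s, unit-peak normalized) at Poisson onsets; 32 Hz.
* **Respiration** — quasi-sinusoid with slow rate modulation; 32 Hz.
* **EEG** — 19 channels (10-20 montage), sum of band-limited noise scaled
  to delta/theta/alpha/beta/gamma power targets, plus shared blink
  transients projected on a frontally weighted topography; 250 Hz.
* **fNIRS** — 20 channels of HbO/HbR: double-gamma HRF pulses (default
  6-s time-to-peak), slow drift, ~1.1-Hz cardiac ripple; HbR anticorrelated
  with HbO; 10 Hz.
* **Eye** — pupil series with blink gaps, plus alternating
  fixation/saccade event streams over four areas of interest; 120 Hz.

Sampling rates are not dictated by the protocol description and were fixed
once at values typical of the named hardware class; all are configurable.

Embedded measures are monotone functions of the epoch's systematic trust
with measure-specific noise (a trusting operator reviews fewer
classifications, agrees more, spends more effort on the secondary map task).
The links are saturating ramps clipped to each measure's natural range so
the extremes of trust land exactly on the documented floor/ceiling.
Counts are binomial over the 3 satellites presented (and 3 map selections
allowed) per 45-s epoch. The per-measure latent noise (SD 0.22 on the
trust scale) keeps embedded measures informative but imperfect proxies —
they are *not* part of the planted sparse support.

Background measures (25 per participant) comprise eight survey subscale
scores — the trust-related ones linear in `delta_p` plus noise —
ten demographic/experience items, sleep, and six psychomotor-vigilance
summaries.

### Missingness

Missingness is flagged per (epoch, stream) slot. The default epoch-level
drop probability, 0.0024, makes the expected missing fraction equal the
0.24% imputation share of the reference protocol. Whole-trial and
whole-session-stream outages (the reference study observed two of the
latter) are available as separate knobs and exercised in tests. Trust
reports are never dropped. Configurations that leave a participant-stream
with no donor session are rejected, because the imputation hierarchy would
be undefined.

### What the generator does not emulate

Epoch-to-epoch autocorrelation of physiological state, sensor-specific
noise spectra, motion artifacts other than EEG blinks and EDA range
violations, gaze position (only AOI labels), learning/fatigue trends, and
any nonlinear or interactive trust structure. Passing recovery tests
therefore show that the pipeline recovers *linear, stationary* structure
through realistic signal processing — not that it would perform identically
on human data.

## Preprocessing

All IIR filtering is 4th-order Butterworth applied forward-backward
(zero-phase). ECG: 1-Hz high-pass, 100-Hz low-pass, 59-61-Hz band-stop.
Respiration: 0.05-3-Hz **band-pass** (the protocol text says "band-stop"
but states the intent of preserving 3-180 breaths/min, which is exactly
0.05-3 Hz). EEG: 0.5-55-Hz band-pass. fNIRS: 0.016-0.5-Hz band-pass per
channel and chromophore.

R-peaks are detected by a derivative-energy envelope (squared derivative,
150-ms moving average), peak-picked with a 200-ms refractory period, then
refined to the local ECG maximum; a signal-to-noise quality flag replaces
manual visual confirmation.

EDA is range-cleaned (samples outside 1-40 µS interpolated — interpolation
rather than deletion keeps the series uniformly sampled for the filters),
Savitzky-Golay smoothed (order 3), and resampled to 10 Hz. The continuous
decomposition estimates the tonic level with a 10th-percentile filter over
an 8-s window followed by a 0.05-Hz low-pass; the phasic component is the
exact remainder, so tonic + phasic reconstructs the input identically. A
sparse SCR driver is recovered from the phasic component by Wiener
deconvolution against the Bateman kernel; events above 0.01 µS are
characterized by onset, amplitude, rise time and half-recovery time, and
candidate events with rise times over 3.5 s are discarded as residual
drift (no Bateman response rises that slowly).

EEG ICA uses FastICA with components auto-rejected when activation kurtosis
exceeds 5 **and** the frontal share of the absolute mixing weights exceeds
0.55 — a reproducible stand-in for manual ocular-component rejection. The
unmixing is estimated on ~4x-decimated data (blink transients are slow) and
applied to the full-rate data; with a full-rank decomposition the
reconstruction of non-rejected activity is exact.

## Features and versions

The frozen dictionary holds 682 base features: ECG 28, EDA 63, respiration
28, EEG 125 (19 channels x 5 bands + 6 region means), fNIRS 360 (20
channels x 9 statistics per chromophore), eye 37, embedded 16, background
25. Gamma-band power is integrated over 30-55 Hz because the EEG chain
low-passes at 55 Hz. The per-feature enumerations of the ECG/EDA/RSP/eye
categories are standard psychophysiology measures frozen to meet the
dictionary's counts.

Eight baseline "versions" map a raw epoch value `a` to a predictor:
difference from or ratio to the trial's pre-trial baseline (v1/v4), the
session's mean pre-trial baseline (v2/v5) or the pre-experimental baseline
(v3/v6); participant z-score (v7) and participant centering (v8). All
eight apply to the psychophysiological categories (156 features); EEG
carries v4 only and fNIRS v1 only; embedded and background enter
unversioned — 1,774 design-matrix columns. Versions 7-8 use participant
statistics computed **from training epochs only** in any train/test
setting, which prevents a leakage path that pooled statistics would open.

Degenerate cells are defined, not infinite: a zero value over its zero
baseline is 1 ("no change"), a nonzero value over a zero baseline is NaN
and enters imputation; a z-score with zero variance is 0 when the value
equals the mean. Without the 0/0 rule, structurally-zero statistics (the
clipped driver's minimum, for instance) would make whole ratio columns
undefined.

Imputation is hierarchical, in order: mean of the trial's other epochs,
mean of the session's other trials, mean of the participant's other
sessions. Observed values are never modified; the provenance level of
every filled cell is recorded; a cell without a donor at any level is a
hard error. Baseline feature tables are imputed the same way first (with a
cross-participant global fallback, since a 45-s resting window can lack
SCRs entirely), so the versioned expansion is always defined.

## Model building

Selection standardizes the design matrix internally and uses a
logarithmic λ grid auto-scaled from λ_max = max|X'y|/n. The grid floor
defaults to λ_max/100: on this data the path below that floor only adds
predictors beyond any fittable model size (the n/5 constraint) at
substantial compute cost. Round 1 runs K-fold cross-validation of the
LASSO path `n_reps` times (fold assignment re-randomized per repetition),
recording the support at the CV minimum-MSE λ and at the 1-SE λ — up to
2 x 50 = 100 sets under the default configuration, unique sets retained.
Round 2 reruns the procedure on the **union** of round-1 features at the
1-SE rule only (the union is chosen over the intersection, which
frequently empties under stochastic folds).

Each unique round-2 set is refit by OLS ("relaxed" step). Exact rank
deficiencies — versions of one feature can be perfectly collinear — are
resolved by pivoted QR, dropping dependent columns with a warning.
Candidates are scored by adjusted R² and by exhaustive leave-one-trial-out
Q² computed with Gram-matrix downdating (one p x p solve per held-out
trial instead of a full refit); LOTO predictions are capped to [0, 1]
before scoring, consistent with the deployment rule, and the Q²
denominator uses the fitting partition's mean. Two anti-overfitting
constraints eliminate candidates: more predictors than n/5 training
observations, or |adjusted R² − LOTO Q²| > 0.2. The survivor with the
highest adjusted R² is selected; ties break toward fewer predictors, then
lexicographic predictor order, for determinism. If every candidate is
eliminated the error says so — constraints are never silently relaxed.

Predictions are clipped to [0, 1]; the count of clipped values is reported
and the raw values remain available.

## Validation harness

LOTOPS (leave-one-trial-out-per-session) withholds one uniformly random
trial per participant-session — 48 trials and 384 epochs (1/6 of the data)
at the default design. Monte-Carlo cross-validation repeats the full
split-select-fit-evaluate cycle 10 times by default and reports per-split
adjusted R², model (LOTO) Q², test Q², RMSE, MAE, predictor count and
capped-prediction count, with mean and SD rows. **MAE is the median
absolute error** — the harness follows that wording deliberately, and a
dedicated test asserts the median. The descriptive ("overall") model runs
the same selection on 100% of the epochs and reports per-category
created/retained feature counts. Per-participant RMSE and
predicted-vs-reported trust traces are produced for one designated split.

## Problem sizes and numerical choices

The full 12x4x6x8 protocol with default selection (50+50 repetitions,
10 folds, 100-λ grid) is the configuration the package defaults express.
The test suite and `scripts/acceptance.py` run the complete pipeline at a
reduced scale — typically 3-4 participants x 2 sessions (288-384 epochs),
5+5 repetitions, 5 folds, 30-λ grid with floor λ_max/33 — chosen so a full
synthetic recovery study runs on one CPU in minutes while leaving the
procedure itself untouched. Structural counts (2,304 epochs, 1,774
columns, 48/384 split sizes, 100 recorded round-1 sets, 239-trial LOTO
sub-fits) are always computed at the full default scale, which is cheap
because raw signals materialize lazily.

Other numerical choices: tolerances of 1e-12 guard ratio/σ denominators;
QR rank detection uses a relative 1e-10 threshold; Welch PSDs use 2-s
segments for EEG and up to 256-sample segments on the 4-Hz-resampled RR
tachogram; the RR spectral bands are the canonical VLF/LF/HF splits
(0.003-0.04-0.15-0.4 Hz), acknowledging that 45-s epochs make VLF
estimates nominal.

## Known limitations

* The selected model is a cohort model; per-participant personalization
  and autoregressive extensions are out of scope.
* Support recovery is assessed against alias groups; a stricter
  single-name criterion is not meaningful under exact proxy collinearity.
* The EDA decomposition is a deconvolution-style re-implementation with a
  reconstruction contract, not a port of any specific toolbox; SCR
  amplitudes agree with planted truth to ~15%.
* The 682-column dictionary's category sum differs by 2 from one printed
  total in the literature this pipeline models (680 vs 682); the
  dictionary follows the per-category table and documents the discrepancy
  rather than resolving it.
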