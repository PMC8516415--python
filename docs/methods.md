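# Methods

## Overview

`somnostage` stages sleep from polysomnography (PSG) in the standard
epoch-by-epoch paradigm: every 30-s epoch of the recording receives one of
the five AASM stages — Wake (W), N1, N2, N3, REM (R) — together with a
probability over all five stages. The classifier is a feature-based
gradient-boosted tree ensemble rather than a deep network: features are
interpretable, training is cheap, and a single EEG channel suffices
(EOG, EMG, age and sex improve accuracy when available).

## Signal conditioning

Channels are resampled to a common analysis rate of 100 Hz (rational
polyphase resampling with an anti-alias FIR; upsampling is refused) and
bandpass-filtered to 0.4–30 Hz. The filter is a Hamming-window linear-phase
FIR applied twice (forward/backward-equivalent, zero net phase), with
transition widths min(low, 2 Hz) at the lower edge and 5 Hz at the upper.
The filter family and order are implementation choices; only the corner
frequencies are fixed by the method. Because the second pass of a symmetric
FIR equals filtering the reversed signal, both passes are evaluated as
centered FFT convolutions with odd-reflection edge padding — the same
response as `filtfilt` at a fraction of the cost on 8-h signals.

Recordings are then cut into complete 30-s epochs; a trailing partial epoch
is dropped, since scoring is defined only on whole epochs. No artifact
rejection is applied before staging.

Amplitude-dependent features assume input in µV. The EDF reader therefore
validates the physical-dimension header field: `uV`/`µV` pass through,
`mV` is converted (×1000), anything else raises rather than silently
guessing a scale.

## Features

Per epoch and per channel (identical sets for EEG, EOG, EMG), 21 features:

*Time domain (10)* — standard deviation, interquartile range, skewness,
kurtosis, number of zero-crossings (strict sign changes; exact zeros carry
the previous sign), Hjorth mobility `sqrt(var(Δx)/var(x))` and complexity
`mobility(Δx)/mobility(x)`, normalized permutation entropy (order 3,
delay 1, normalized by log 3! so monotone signals score 0 and white noise
≈ 1), and two fractal dimensions: Petrosian (zero-crossings of the first
difference) and Higuchi (curve-length scaling, k_max = 10).

*Frequency domain (11)* — relative power in six contiguous bands
partitioning 0.4–30 Hz (slow 0.4–1, delta 1–4, theta 4–8, alpha 8–12,
sigma 12–16, beta 16–30 Hz), the log10 absolute broadband power, and four
ratios formed from the relative powers (delta/theta, delta/sigma,
delta/beta, alpha/theta, each with a 1e-12 denominator guard). Spectra use
Welch's method with a 5-s Hamming window, 50 % overlap (0.20 Hz bin
spacing) and *median* averaging over segments, which is robust to transient
artifacts. A frequency bin belongs to the band whose half-open interval
[low, high) contains its center; the last band is closed at 30 Hz, so the
six relative powers always sum to exactly 1.

Degenerate (exactly flat) epochs are guarded: std, iqr, zero-crossings,
Hjorth parameters, skewness, kurtosis and permutation entropy report 0 and
the Higuchi dimension reports 1, keeping every output finite.

## Temporal context and normalization

Human scorers use surrounding minutes of context. Each raw feature is
duplicated twice:

1. a 7.5-min centered triangular-weighted rolling average — 15 epochs with
   weights [0.125, 0.25, …, 1.0, …, 0.25, 0.125]; at night edges the window
   truncates to in-range epochs and renormalizes its weights (no padding
   artifacts at lights-on/off);
2. the unweighted mean of the 2 min (4 epochs) strictly *before* the
   current epoch; at epoch 0, where no history exists, the current value is
   used.

Both smoothed duplicates are then z-scored across the night (each subject
is their own reference, absorbing inter-individual amplitude and spectral
offsets; zero-variance columns map to zeros). The raw columns are kept
untouched so absolute µV-scale information and single-epoch specificity
survive. Two covariates complete the matrix: `time_elapsed` =
epoch_index/(n−1) ∈ [0, 1] (sleep-stage composition is asymmetric across
the night) and, optionally, constant `age` (years) and `sex` (1 = male,
0 = female) columns. With EEG+EOG+EMG and no metadata this yields
3 × 21 × 3 + 1 = 190 columns. Nights shorter than the centered window still
process, with full window truncation.

## Classifier

A LightGBM multiclass model with 500 estimators, maximum depth 5, 90
leaves, and a 60 % feature fraction per tree. Class imbalance (N2 ≈ half of
a night, N1 ≈ 5 %) is countered with per-sample weights keyed by stage:
{N1: 2.2, N2: 1.0, N3: 1.2, R: 1.4, W: 1.0}. Training is deterministic
given a seed (`deterministic=True`, single thread). Unscored epochs are
excluded from training; predictions are the canonical-order argmax of the
stage probabilities, ties resolving to the earlier stage; the per-epoch
confidence is the row maximum (≥ 0.2 by construction over 5 classes).

Hyperparameter selection is a 3-fold cross-validated grid search scored by
`|acc_train − acc_test| + 4·(1 − acc_test)` — held-out accuracy dominates
but a train/test gap (overfitting) is penalized. The class-weight search
space is the Cartesian product N1 ∈ {1.6, 1.8, 2.0, 2.2}, N2 ∈ {0.8, 0.9,
1.0}, N3/R/W ∈ {1.0, 1.2, 1.4} (324 combinations), scored by the mean of
accuracy and macro-F1.

Feature importance aggregates exact TreeSHAP attributions (LightGBM's
`pred_contrib`): absolute per-epoch attributions are summed within each
stage output and the five per-stage sums averaged, one nonnegative score
per feature. If a model backend cannot produce contributions the importance
falls back to split gain with a logged warning.

Models persist as versioned compressed joblib archives embedding the exact
feature-name list and a configuration hash; prediction refuses mismatched
feature sets, and a model directory can be keyed by the sorted
channel-role + metadata signature (e.g. `age+eeg+eog+sex`) for automatic
selection.

## Consensus scoring

Given ≥ 3 scorers, the consensus stage at an epoch is the plurality vote;
vote ties are broken by the *most reliable* scorer — the one with the
highest mean pairwise agreement with the other scorers for that night
(agreement computed over mutually scored epochs only; reliability ties go
to the lowest scorer index for determinism). For unbiased evaluation of an
individual scorer, the leave-one-out consensus excludes that scorer and
tie-breaks with the most reliable of the rest (requires ≥ 4 scorers).
Epochs unscored by some scorers are voted among those who scored them; an
epoch unscored by all stays unscored.

## Evaluation

All metrics derive from a 5×5 confusion matrix over jointly scored epochs:
accuracy, Cohen's kappa (with the chance-agreement = 1 guard), the
multiclass Matthews correlation coefficient, per-stage one-vs-rest F1 and
macro-F1 over stages present. Stratified accuracies split epochs by
distance to a reference stage change (an epoch is a "transition epoch" if a
change occurs within ±1.5 min, i.e. a boundary between epochs b and b+1
flags epochs b−2 … b+3; the precise index convention is a documented
choice) and by classifier confidence ≥ 0.80 vs below. Among misclassified
epochs, second-choice accuracy is the fraction whose runner-up probability
stage was correct. Holm's step-down adjustment is provided for families of
paired comparisons.

## Synthetic data

The generator makes the pipeline testable without clinical recordings.

*Hypnograms* follow a first-order Markov chain over the five stages with
strong self-transitions (default night 960 epochs = 8 h), started in Wake.
A time-inhomogeneity factor (default 0.4) scales the probability of moving
into N3 by (1 + 0.4·(1−2f)) and into R by the complement, f being
normalized night time — deep sleep concentrates early and REM late, as in
real nights. The default chain's long-run distribution is ≈ 21 % W, 10 %
N1, 36 % N2, 18 % N3, 16 % R with ≈ 12–14 % of epoch pairs crossing a
stage boundary, both in the range of real overnight PSG.

*Signals* are colored Gaussian noise: each epoch's spectrum is piecewise
flat over the six analysis bands, matching a per-stage, per-role band
profile, scaled to a per-stage RMS in µV. Default profiles encode the
classical stage signatures — delta-dominant high-amplitude N3, a sigma
(spindle-band) bump in N2, alpha-rich Wake, low-amplitude mixed-frequency
N1 and REM, slow-deflection-rich EOG in REM, and an EMG amplitude drop in
REM (atonia). Three mechanisms give the data realistic difficulty rather
than trivial separability: lognormal per-epoch amplitude jitter (σ = 0.25),
lognormal per-band profile jitter (σ = 0.4, renormalized) that makes
neighbouring stages overlap spectrally, and transition blending (weight
0.3) that mixes an epoch's profile with its neighbours' stages so epochs at
stage boundaries are genuinely ambiguous — which is where both humans and
the classifier err on real data.

What the generator does *not* emulate: discrete microstructure (spindle or
K-complex waveforms, slow-wave morphology, phasic REMs), artifacts,
arousals, apnea events, and realistic autocorrelation beyond band power.
Passing the end-to-end benchmark therefore shows that the pipeline
correctly learns stage-conditioned spectral/amplitude structure and
reproduces the qualitative orderings (stable > transition accuracy,
high-confidence > low-confidence accuracy); it does not certify accuracy
on clinical recordings.

*Scorer panels* corrupt a ground-truth hypnogram independently per scorer
at a configurable error rate, drawing wrong labels from an adjacent-stage
kernel (W↔N1, N1↔{W, N2}, N2↔{N1, N3}, N3↔N2, R→{N1, W}), so simulated
disagreements resemble plausible human confusions and every corruption
changes the stage.

All randomness derives from one integer master seed through
`numpy.random.SeedSequence` substreams (per night, per channel, per
scorer), so whole experiments reproduce bit-identically.

## Problem sizes and numerical choices

The built-in benchmark trains on 20 synthetic nights and evaluates 5
held-out nights (960 epochs each), a size chosen so the whole experiment —
generation, feature extraction, training, evaluation — completes in a few
minutes on one CPU while leaving thousands of held-out epochs per metric.
Probability rows are validated to sum to 1 within 1e-9 (renormalized after
CSV round-trips, where 6-decimal printing perturbs them); the six relative
band powers are validated to partition within 1e-6; reliability ties use a
1e-12 tolerance so summation order cannot flip the documented lowest-index
tie-break. EDF export quantizes to 16 bits against per-channel symmetric
physical ranges, bounding round-trip error by one quantization step.

## Known limitations

- The boosting library's internal details beyond the four stated
  hyperparameters (e.g. learning rate) are left at library defaults.
- Consensus reliability is computed on scored epochs only.
- Sub-30-s resolution staging, event detections, and probabilistic
  (latent-class) consensus models are out of scope.
- The synthetic benchmark's absolute accuracy (~0.95+) exceeds what is
  attainable on clinical data; only the qualitative structure transfers.
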