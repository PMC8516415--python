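# somnostage

Feature-based automated sleep staging for polysomnography (PSG), with
consensus scoring and epoch-by-epoch evaluation — for sleep researchers and
engineers who need reproducible, interpretable hypnograms from overnight
EEG/EOG/EMG recordings without a GPU or cloud upload.

## What it does

Every 30-s epoch of a night is assigned one of the five AASM stages
(W, N1, N2, N3, R) plus a probability vector and a confidence score:

1. **Conditioning** — channels are resampled to 100 Hz and bandpass-filtered
   0.4–30 Hz (zero-phase FIR), then cut into 30-s epochs.
2. **Features** — per epoch and channel: std, IQR, skewness, kurtosis,
   zero-crossings, Hjorth mobility/complexity, permutation entropy,
   Petrosian and Higuchi fractal dimensions; Welch relative band powers in
   slow/delta/theta/alpha/sigma/beta, broadband log-power, and four band
   ratios (median-averaged 5-s Hamming windows, 0.20 Hz resolution).
3. **Context** — each feature is duplicated through a 7.5-min centered
   triangular rolling average and a 2-min trailing average, both z-scored
   per night; `time_elapsed` ∈ [0, 1] and optional age/sex covariates are
   appended.
4. **Classification** — a LightGBM gradient-boosted ensemble
   (500 trees, depth 5, 90 leaves, 60 % feature fraction) with per-stage
   sample weights {N1: 2.2, N2: 1, N3: 1.2, R: 1.4, W: 1} against stage
   imbalance. Confidence = max stage probability.
5. **Evaluation & consensus** — confusion matrices, accuracy, Cohen's κ,
   MCC, per-stage/macro F1, transition- and confidence-stratified
   accuracies, Holm-adjusted comparisons; majority-vote consensus over
   multiple scorers with a most-reliable-scorer tie-break and unbiased
   leave-one-out consensus.

A synthetic PSG generator (Markov-chain hypnograms with early-N3/late-REM
asymmetry; stage-conditioned colored-noise signals with realistic spectral
overlap) makes everything testable without clinical data. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```bash
# generate two synthetic nights (EDF + reference hypnogram CSV)
somnostage synth --out-dir demo --nights 2 --n-epochs 960 --seed 3

# train on night 0
somnostage train --edf demo/night000.edf --hypnogram demo/night000_hypno.csv \
    --eeg C4-M1 --eog EOG-L --emg EMG-Chin --out demo/model.joblib --seed 42

# stage night 1 and evaluate against its reference
somnostage stage --edf demo/night001.edf --model demo/model.joblib \
    --eeg C4-M1 --eog EOG-L --emg EMG-Chin --out demo/pred.csv
somnostage evaluate --ref demo/night001_hypno.csv --pred demo/pred.csv
```

The evaluation prints (exact numbers vary with the epochs of the night):

```
epochs evaluated : 120
accuracy         : 0.8417
Cohen's kappa    : 0.7583
MCC              : 0.7677
macro F1         : 0.7700
per-stage F1     : W=0.667  N1=0.682  N2=0.905  N3=0.930  R=0.667
confusion (rows=ref, cols=pred, order W/N1/N2/N3/R):
       6      0      0      0      0
       6     15      0      0      0
       0      7     57      3      2
       0      0      0     20      0
       0      1      0      0      3
transition vs stable accuracy: 0.8243 vs 0.8696
confidence ≥0.80 vs below: 0.8505 vs 0.7692
second-choice accuracy on errors: 0.8421
```

Accuracy is the fraction of epochs where prediction and reference agree;
κ and MCC correct for chance and stage imbalance; the stratified lines show
the characteristic pattern that errors cluster near stage transitions and
in low-confidence epochs, and that when the classifier errs, its
second-ranked stage is usually the right one.

The same functionality is available as a library
(`somnostage.stage_recording`, `somnostage.train_nights`,
`somnostage.consensus_hypnogram`, …), and `somnostage consensus` builds a
majority-vote reference from three or more scorer hypnogram files.

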