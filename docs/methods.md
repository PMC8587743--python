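# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic test bed does and does not show.

## Signal model and preprocessing

All processing operates on uniformly sampled single-channel strips
(`Signal`): sample `i` occurs at `t0 + 1000·i/fs` ms. Indices are 0-based,
times are milliseconds, and every interval in the package is half-open
`[start, end)` — one convention end to end avoids off-by-one drift between
segmentation, annotation and feature code.

Bandpass filtering uses Butterworth designs applied forward-backward
(`sosfiltfilt`). The zero-phase choice matters because downstream features
are functions of beat *times*: a causal filter would delay peaks by a
modality- and rate-dependent lag. The ECG band (order 2, 8–20 Hz) removes
baseline drift and de-emphasizes P/T waves while keeping most QRS energy;
the PPG band (order 3, 0.5–8 Hz) keeps the pulse wave while removing drift
and mains interference. Filtering precedes FFT resampling to the working
rate; with a 20 Hz upper edge below the 25 Hz Nyquist of the 50 Hz working
rate the order is mathematically immaterial, but it is fixed for
reproducibility.

The working rate defaults to 50 Hz — the lowest rate at which time-domain
HRV can still be recovered with small error, and a rate any consumer PPG
sensor can deliver. `resample_fft` produces exactly `round(n·target/fs)`
samples (Fourier-domain resampling truncates, it does not alias; a 50/60 Hz
mains residual is measured in tests as the chain response to the
interference alone, exploiting linearity).

Feature matrices are standardized to zero mean and unit *sample* (n−1)
standard deviation per column. Stats are fit on the training partition only
and applied elsewhere; fitting them globally leaks information from test
rows into the scaler, so the global variant exists only behind an explicit
`--global-norm` flag. A constant column gets sd 1 (with a warning) so it
maps to zeros rather than NaNs.

## Beat detection

The detector compares two centered moving averages of the (optionally
clipped and squared) signal: `MA_peak` with window `W1` and `MA_beat` with
window `W2`, both converted from milliseconds to an odd number of samples.
Contiguous runs where `MA_peak > MA_beat` are candidate blocks; blocks
narrower than `α = W1 + β` samples are rejected (β defaults to 0), and the
argmax of the *original filtered* signal inside each surviving block is the
beat (earliest index on ties, so reported amplitudes are physical and
deterministic). Defaults: ECG `W1` = 100 ms, `W2` = 525 ms, no squaring;
PPG `W1` = 111 ms, `W2` = 667 ms, with squaring — squaring sharpens the
systolic/diastolic contrast and is unnecessary for the already-narrow QRS.

Numerical and edge policies, all of which the underlying block algorithm
leaves open:

- Moving averages use reflection padding; centered windows keep block
  centers aligned with peaks (a trailing window would bias times by up to
  `W1/2`).
- Negative samples are clipped to zero before averaging in both variants, so
  negative filter lobes cannot suppress `MA_peak`.
- Width thresholding is the only rejection rule, plus two guards: blocks
  whose maximum is below `1e-10 ×` the signal maximum are discarded
  (template tails at denormal magnitude can otherwise open junk blocks on
  silent stretches; the relative threshold preserves amplitude-scale
  invariance), and blocks touching the first or last sample are discarded
  because they are dominated by filter and padding transients. A separate
  lower amplitude bound on blocks is sometimes described for this detector
  family but never given a formula; it is intentionally left out beyond the
  numerical guard.
- Rates below 50 Hz are refused: `W1` would fall under 3 samples and the
  two averages lose their scale separation.

Detection demands a bandpass-filtered input. On unfiltered synthetic ECG the
T wave carries enough low-frequency mass to open its own blocks; the 8–20 Hz
band removes it (a Gaussian bump with σ = 70 ms has essentially no energy
above 8 Hz).

## HRV features

Twelve time-domain statistics per strip, in the fixed order
`meanRR, medianRR, madRR, mcvRR, SDRR, rMSSD, CVRR, CVSD, RR20, pRR20,
RR50, pRR50`. Conventions that needed fixing:

- rMSSD includes the square root (its defining name), with the `N−1`
  divisor over successive differences; SDRR is the sample (n−1) standard
  deviation.
- `pRR20`/`pRR50` divide the threshold counts by the total number of
  intervals `N`; the conventional pNN-style `N−1` divisor is available via
  `prr_denominator="n-1"`.
- `CVSD = rMSSD / meanRR`, the standard definition of the coefficient of
  variation of successive differences.
- `madRR` is the raw median absolute deviation (no 1.4826 consistency
  factor); `mcvRR = madRR / medianRR`.
- Threshold counts use strict inequalities (differences *exceeding*
  20/50 ms).
- A strip must yield at least 5 beats (4 intervals); medians and successive
  differences are meaningless below that, and such windows are dropped and
  logged upstream.

## Segmentation and labeling

Records are tiled into consecutive non-overlapping 30-s windows; the
trailing partial window is discarded. A window wholly inside one rhythm
interval inherits its label. Windows touching excluded rhythms (anything
mapped to OTHER — paced rhythms, bigeminy, etc.) are dropped, as are windows
straddling an NSR/AF boundary: a mixed window has no honest single label.
Windows not already labeled AF are re-examined against beat annotations:
if every beat is in the N (`N,L,R,B`) or S (`A,a,J,S,j,e,n`) alphabet, at
least one S beat is present, and the S fraction strictly exceeds 0.5, the
window is treated as AF — the supraventricular-ectopy saturation rule, with
"over 50%" read as a strict inequality. Saturation never overrides an AF
rhythm label (it cannot change it) and is only consulted for non-AF windows.
A beat belongs to the window containing its annotation time under the
half-open convention.

Record-level thinning of pure-NSR records (the class balance knob) is a
seeded configurable fraction; the original record selection was arbitrary
and cannot be reproduced exactly.

## Classifier

Architecture (input: the 12 features as a length-12, single-channel
sequence): Conv1D 256 → BN → Conv1D 128 → BN → Conv1D 64 → BN → Conv1D 32 →
BN → Dropout 0.2 → MaxPool 2 → Flatten (192) → Dense 8 (ReLU) → Dense 1
(sigmoid); all convolutions kernel 3, stride 1, ReLU, 'same' padding (valid
padding would shrink 12 → 4 before pooling and make the depth fragile).
Training: Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), binary cross-entropy
(the only loss consistent with a scalar sigmoid output), batch 16, 50
epochs, decision threshold 0.5, AF as the positive class.

The layers and optimizer are implemented in NumPy (convolution via im2col
matrix products; fused sigmoid–cross-entropy gradient for stability; Glorot
uniform initialization, all randomness from a single `random_state`).
Implementation choices worth noting:

- Batch-norm running statistics use momentum 0.9. With the corpus sizes this
  package targets, training runs span only tens to hundreds of optimizer
  steps; a 0.99 momentum leaves the inference-time statistics dominated by
  their initialization, which biases every sigmoid output to one side of
  0.5 even when the ranking (AUC) is perfect. 0.9 converges within tens of
  steps and matches the small-data regime.
- Evaluation protocol: stratified 80/20 outer split; stratified 5-fold CV
  inside the 80% (each fold trains a fresh seeded model); a final model
  refit on the full 80% is evaluated once on the untouched 20%.
- Finetuning continues training *all* weights of a copy of the trained model
  at `lr × 0.1` for 20 epochs (the reduced rate and epoch count are this
  package's defaults; the source protocol states neither), under a
  stratified 4-fold scheme so every target-modality instance is tested
  exactly once by a model that never trained on it. Z-score stats are refit
  on each fold's training portion by default; reusing the source-modality
  stats is a flag (`scaler_policy="reuse"`), and pre-finetune evaluation of
  the frozen model uses exactly that reuse policy, since no target training
  portion exists in that scenario.
- AUC is the rank-based (Mann–Whitney) statistic with half credit for ties,
  cross-checked in tests against an independent implementation.

## Synthetic data

The generator is the package's study population; its defaults are frozen.

- **NSR RR model**: stationary AR(1) around 926 ms with sd 90 ms (the
  short-term normative mean ± sd for healthy adults; normative rMSSD range
  19–75 ms, SDRR 32–93 ms) and lag-1 correlation ρ = 0.7, floored at
  400 ms. ρ was chosen so the successive-difference statistics land inside
  the normative rMSSD band given sd 90 ms: rMSSD ≈ sd·√(2(1−ρ)) ≈ 70 ms.
- **AF RR model**: no published AF RR distribution exists to copy, so this
  is explicit synthetic scaffolding expressing the defining physiology —
  irregular, essentially uncorrelated intervals: i.i.d. Gaussian mean
  700 ms, sd 180 ms, mixed with weight 0.2 of uniform(350, 1400) ms jumps,
  floored at 300 ms. It produces cohort rMSSD ≈ 300 ms and pRR50 > 0.8,
  i.e. unambiguous AF-like irregularity.
- **Waveforms**: ECG beats are Gaussian QRS bumps (σ 20 ms, unit amplitude)
  with small P (0.12, σ 30 ms, −180 ms) and T (0.25, σ 70 ms, +220 ms)
  bumps; PPG beats are systolic (σ 60 ms, amplitude 1) plus diastolic
  (σ 90 ms, amplitude 0.4, +250 ms) Gaussians. Noise options: white noise by
  SNR, 0.3 Hz baseline wander, 50/60 Hz mains (injected at the native rate,
  so the filter chain is exercised realistically), and 1-s motion bursts.
- **Shifted PPG cohort** (the transfer-learning target): NSR mean 820 ms,
  sd 150 ms, ρ 0.25 — wrist PRV under motion artifact is noisier and faster
  than clinical NSR — and AF mean 780 ms, sd 150 ms, jump weight 0.1, i.e.
  less extreme than the ECG-archive AF. The shift moves normal-rhythm
  variability toward the AF side, which degrades the frozen ECG-trained
  model (observed pre-finetune accuracy ≈ 60–75%) and is recoverable by
  finetuning.
- Corpora are exact 30-s strips with the first beat at 300 ms; per-segment
  seeds derive deterministically from the corpus seed, and the manifest
  (class, seed, true peak times, true-RR features) is byte-identical across
  runs of the same spec.

What the synthetic bed does *not* emulate: real QRS morphology variants and
ectopic beat shapes, PPG waveform changes with vascular tone and skin
optics, non-stationary noise, annotation errors, and within-patient
correlation across strips (splits are per-strip, matching the source
protocol; a record-grouped split is a planned extension). Passing tests
therefore demonstrate correctness of the pipeline and the learnability of
interval-statistic separation, not clinical performance.

## Problem sizes

Default study sizes were chosen as the smallest that make the statistics
stable: the classifier study uses 200 + 200 ECG strips (holdout 80) and
five 100 + 100 shifted PPG cohorts for the finetune comparison; detector
recovery sweeps 40–180 bpm noiselessly for both modalities and runs 100
seeded trials at 20 dB SNR; formula oracles use 1000 random series. The
full-database protocol (thousands of strips from public ECG archives and an
access-restricted wrist-PPG set) is out of desk scope; an optional script
runs it when local WFDB data are supplied.

## Known limitations

- The WFDB support is a minimal dialect: formats 16 and 212, one annotation
  file per record, standard beat codes and rhythm aux strings. It is not a
  general PhysioBank client.
- The saturation rule's interaction with rhythm labels is interpreted
  conservatively (never overriding AF; mixed windows dropped); other
  readings are defensible.
- The detector reports no confidence; strips with fewer than 5 detected
  beats are dropped rather than flagged for review.
- Finetune hyperparameters (epochs, lr multiplier) are package defaults,
  not published values; both are exposed in `TrainConfig`.
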