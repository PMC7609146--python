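# Methods

This note documents the models, defaults and numerical choices behind
ecgkit, and what the synthetic experiments do and do not establish.

## Synthetic ECG generator

Each beat is a sum of Gaussian wave components placed relative to the R
position — amplitude a_w (mV), width b_w (s) and offset θ_w (s) for
w ∈ {P, Q, R, S, T}:

    x(t) = Σ_w a_w · exp( −(t − t_R − θ_w)² / 2b_w² )

with MLII-like defaults (P 0.15 mV/25 ms at −180 ms, Q −0.10, R 1.00,
S −0.20 around ±35 ms, T 0.30 mV/60 ms at +280 ms). This is the same
parameterization family as the classic dynamical ECG simulators, kept in
the time domain so QRS width is directly controllable.

Beat scheduling runs on a sinus clock with RR = 60/HR, HR ~ N(hr_mean,
hr_sd) clipped to [25, 220] bpm. Per beat (outside AF):

- **PVC** (probability `pvc_rate`): fires 45% early, QRS widths and
  offsets doubled (≥1.8× normal width), no P wave, discordant (inverted)
  T, and a full compensatory pause — the sinus clock keeps running, so
  the pause completes two RR.
- **PAC** (probability `pac_rate`): fires 25% early with a halved,
  earlier P wave, and resets the sinus clock (non-compensatory).
- **AF segments**: i.i.d. lognormal RR with the configured coefficient
  of variation (default 0.25) and no P wave; the lognormal is the
  simplest RR model that makes irregularity detectors identifiable.
  Rhythm transitions carry "(AFIB" / "(N" aux labels.

Noise kinds: baseline wander (sinusoid ≤ 0.5 Hz), powerline (50 Hz), and
white Gaussian, each rescaled so the realized SNR equals the request
exactly; `snr_db = inf` is the no-noise sentinel. Default conditions used
throughout the tests: 360 Hz sampling, 60–80 bpm means, hr_sd 2–3 bpm,
ectopy rates of 0.1 where ectopy is under test — values a reviewer of
ambulatory recordings would recognize as unremarkable.

**What the generator does not emulate:** real QRS morphology families
(bundle-branch blocks, paced beats), fibrillatory f-waves, electrode
motion artifacts, respiration modulation, or inter-patient morphology
variability beyond global amplitude scaling. Passing results on these
fixtures demonstrate correctness of the pipeline mechanics and
separability-driven learning, not clinical-grade performance on real
recordings.

## WFDB/MIT codecs

Headers, format-212 (packed 12-bit pairs) and format-16 signal files, and
MIT annotation files (10-bit time deltas with 6-bit codes; SKIP for gaps
over 1023 samples; AUX rhythm strings; NUM/SUB/CHN parsed and discarded)
are implemented directly against the format specification and validated
against independent byte-level oracles in the tests. Indices are 0-based
samples everywhere. Writers are exact inverses of readers (round-trip
equality is a test invariant). Out of scope: multi-segment records, EDF,
compressed formats; unsupported signal formats raise.

## Preprocessing

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(zero phase), default band 0.5–40 Hz — standard ambulatory practice. The
quality score is the in-band fraction of Welch-PSD power of the
mean-removed window, clamped to [0, 1]; flatline (variance < 1e-6 mV²)
and clipping (≥1% of samples pinned at the rails with a non-trivial
range) zero the score, and scores below 0.2 mark a segment unusable.
These thresholds are toolkit constants, chosen once on synthetic
fixtures.

## QRS detectors

**Pan–Tompkins.** Stages as in the classical description (band-pass 5–15
Hz, five-point derivative, squaring, 150 ms moving-window integration,
dual adaptive thresholds, 200 ms refractory, T-wave slope test within
360 ms, search-back at 1.66× average of the last 8 RR). Deviations worth
noting: filtering is zero-phase (filtfilt) and the derivative/integration
kernels are centered, so no stage introduces group delay and detections
are translation-equivariant in steady state; detected integration peaks
are refined to the extremum of |signal − local median| within ±50 ms,
which handles negative-going (PVC-like) complexes; a final pass enforces
the refractory spacing keeping the larger-amplitude peak.

**Image-based CNN.** Windows of 0.25 s at 0.05 s stride are rasterized to
64×64 binary images (amplitude min–max scaled per window, one trace pixel
per column, vertically connected). The network is 8 conv layers by
default (3×3 kernels, stride-2 every second layer while the spatial size
exceeds 4, channels 4→32, global average pooling, 2-way softmax), with
depth configurable to 32. Training uses Adam at 3e-3 for 6 epochs, batch
32, all randomness seeded; positive windows are jittered by up to one
stride so that every on-grid window near an R peak is in-distribution.
At inference each window's probability covers its center ± one stride
(twofold overlap averaging); local maxima of the trace above 0.5 with
200 ms separation, refined to the signal extremum within ±50 ms, are the
detections, with the trace value kept as confidence. Window size, image
resolution, loss and splits are toolkit decisions; depth 8 rather than 32
is the desk-scale default because the shallower net already saturates the
synthetic task and trains in seconds on one CPU.

## Beat classification

Features per beat: waveform resampled to 64 points and scaled by the
record's median |R| amplitude, plus RR_prev, RR_next (scaled by record
median RR; NaN edge sentinels imputed to 1) and QRS width (scaled by
record median). QRS width is the contiguous span around R where
|signal − baseline| ≥ 25% of the R amplitude, searched within ±200 ms.

The primary model is a single-layer bidirectional LSTM (hidden 16 per
direction, forget-gate bias 1, Adam 0.01, 30 epochs, sequences processed
in chunks of 128 beats) with a per-beat 3-way softmax; backpropagation
through time is implemented in numpy and is exactly reproducible given
the seed. Baselines are multinomial logistic regression and a linear-SVM
(decision scores softmaxed into pseudo-probabilities for the ambiguity
queue). `train_and_select` trains each candidate with a shared seed and
picks the validation-accuracy argmax, ties toward the earlier candidate.
The label alphabet is fixed to {N, V, A}; fusion/paced/unknown beats are
mapped to N for rhythm purposes.

Patient adaptation fine-tunes a copy of the BiLSTM for 4 epochs at 0.3×
the training rate on the labeled leading window of a recording. The
adapted copy is kept only if its accuracy on the adaptation set itself
did not decrease, so the non-degradation guarantee holds independent of
fine-tuning dynamics, and the base model is never mutated.

## AF detection

RR-based, classifier-free: windows of 30 intervals are flagged when
median(|ΔRR|)/median(RR) > θ₁ = 0.08 **and** the Shannon entropy of the
8-bin RR histogram, normalized by log₂ 8, exceeds θ₂ = 0.7. The histogram
bins span median ± 37.5% so that near-constant RR concentrates in one or
two bins (low entropy) regardless of how small its absolute spread is;
the combination makes slow rate drift (low Δ statistic) and occasional
ectopy (low entropy) non-AF. Thresholds are toolkit defaults tuned on
synthetic fixtures. Flagged windows are merged, so episode boundaries are
resolved only to about one window; with 30-beat windows this is ±20–25 s
at typical rates, visible as boundary slack in the worked example.
Detection from RR alone cannot distinguish AF from other irregularly
irregular rhythms; on real data this is a screening statistic, not a
diagnosis.

## Evaluation conventions

Matching is greedy in ascending reference order — each reference beat
takes the nearest unmatched test beat within the tolerance (150 ms
default; ties toward the earlier beat). On streams whose inter-beat
spacing exceeds twice the tolerance this greedy matching is provably
maximum-cardinality, which the tests verify against an independent
bipartite-matching oracle on 1000 random instances. Counts are conserved
(TP+FP = detections, TP+FN = reference beats); undefined ratios are
reported as NaN with a warning, never silently 1.

Acc is defined as TP/(TP+FP+FN), the unique definition consistent with
the published module table via the identity Acc = (1/Se + 1/P+ − 1)⁻¹
when TP > 0. Per-record tables round percentages to two decimals (halves
away from zero) and average the per-record percentage columns rather than
pooling counts, matching the published per-record table convention. The
published module table's own aggregate F1 equals f(mean Se, mean P+), not
the mean of the F1 column — both are computable here; `benchmarks`
documents this and the three rows whose F1 values are transposed between
the method columns in print.

## Problem sizes and determinism

The test suite and acceptance script size their simulations for a single
CPU: five-minute records for detector performance (seeds 0–4, SNR 20/10/
5/0 dB), ~2000-beat records for classifier recovery (seeds 0–4), one
600 s record at 50% AF burden for episode overlap, and a 4-minute record
(~630 windows) for CNN training. Every stochastic component takes an
explicit seed, and identical seeds give bitwise-identical simulations and
training trajectories.

## Known limitations

- Pan–Tompkins at 0 dB *white* noise remains near-perfect here because
  the 5–15 Hz band removes most broadband power; this does not bound
  performance under structured artifacts (motion, muscle noise), which
  the generator does not produce.
- The CNN detector must be retrained per sampling rate (inference
  enforces the training fs), and its window scoring is only calibrated
  near the stride used in training.
- The published per-record/per-module absolute figures were produced on
  data and trained weights that were never released; this toolkit
  verifies their internal arithmetic and reproduces the *methodology* on
  synthetic data rather than those absolute values.
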