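# Methods

## Problem and pipeline

`dmdeeg` classifies dementia (AD, FTD) against controls (CN) from short
eyes-open (EO) EEG recorded during photic stimulation. EO EEG suppresses the
posterior alpha rhythm and destabilizes low frequencies, so instead of
long-window spectrograms the pipeline decomposes short windows with Hankel
(time-delay) Dynamic Mode Decomposition and lets a 3D CNN read the
segment-to-segment evolution of the resulting mode maps:

1. **Eligibility.** A recording enters the analysis iff its stimulus-on
   interval is strictly longer than 30 s. On the published 88-subject
   stimulus table this retains 84 recordings (35 AD / 22 FTD / 27 CN).
2. **Epoching.** Each eligible interval contributes exactly 10 partially
   overlapping 24-s epochs. Start times are evenly spaced over
   `[onset, offset − 24]`; even spacing is the unique scheme that uses the
   full interval, equalizes overlap, and gives every subject the same epoch
   count. Time → sample conversion is `floor(t·fs)` with half-open windows.
3. **Segmentation.** Each epoch splits into 12 contiguous, non-overlapping
   2-s segments (19 × 1000 samples at 500 Hz).
4. **DMD.** Each segment is shift-stacked into an `(M·S) × (N−S+1)` Hankel
   matrix (S = 48 → 912 × 953 for 19 channels), the least-squares propagator
   is eigendecomposed through a rank-R SVD surrogate (R = 100), and modes
   with eigenfrequency `ω = Im(log λ)/(2πΔt)` inside the passband
   (4–40 Hz main analysis; 0.5–40 Hz for the delta-retaining variant) are
   kept, sorted by ascending frequency.
5. **Imaging.** The channels × retained-modes magnitude matrix is bilinearly
   interpolated (corner-aligned grid) to 50 × 50 and min-max rescaled to
   [0, 1]; 12 consecutive segment images stack into one 50 × 50 × 12 tensor.
6. **Classification.** A 3D CNN (three conv blocks of 16/32/64 3×3×3 filters
   with batch norm, ReLU, and 2×2×2 ceil-mode max pooling; dropout 0.25;
   dense 128/64 with dropouts 0.20/0.25; 2-logit softmax) is trained with
   Adam (lr 5·10⁻⁴, batches of 16, ≤ 75 epochs, cross-entropy). Input
   z-scoring uses per-voxel statistics of the training split only.
7. **Evaluation.** Subject-wise leave-N-subjects-out: five batches, each an
   independent seeded split of every group into five near-equal partitions;
   five folds per batch (one partition per group held out); five training
   repetitions per fold. Metrics come from the cumulative confusion matrix;
   "Total" rows are unweighted macro averages; batch accuracies feed a
   t-based 95% CI; the delta-band ablation is a paired t-test over
   (batch, fold) accuracy pairs (df = 24 for the full protocol).

A matched FFT baseline replaces step 4 with per-channel Hann-periodogram
PSDs in dB (10·log₁₀(power + 10⁻²⁰)) over 12 four-second windows per epoch,
band-restricted and rastered to the identical tensor geometry, so the
classifier is feature-agnostic.

## Mode-map weighting

The eigendecomposition of the reduced operator returns unit-norm
eigenvectors, so raw exact-DMD mode columns (`Φ = Y₂VΣ⁻¹W`) all carry
comparable norm no matter how much signal they represent; the energy
bookkeeping sits in the amplitudes `c` (from `min‖Φc − y₁‖`) and in `|λ|`,
which governs within-window growth or decay. A magnitude map built from
`|φ|` alone is therefore nearly flat across modes and carries topography but
almost no spectral contrast. `mode_map` consequently scales each retained
column by `|c_j| · mean_k |λ_j|^{k−1}` — the mode's average amplitude over
the fitted snapshots — so that a column's brightness tracks the mode's
actual contribution to the segment and fast-decaying noise modes recede
relative to sustained oscillations. On synthetic cohorts this weighting is
what makes the planted rhythms (theta in the AD-like group, posterior alpha
in controls) dominate the maps; the alternatives (`"amplitude"`, `"none"`)
remain available for comparison. Because the scaling is per column, it does
not affect eigenfrequencies, column ordering, or within-column topography.

## Choices where the design was open

- **Exclusion boundary.** Retain iff duration > 30 s. The two printed
  formulations ("≤ 30 s excluded", "longer than 30 s retained") are both
  satisfied by the strict rule, which reproduces the four known exclusions
  (two of them sit exactly at / within 0.01 s of 30 s).
- **Epoch overlap pattern.** Even spacing (above); the source analysis names
  only a "partially overlapping sliding window".
- **FFT window count.** A literal 2-s step of 4-s windows over 24 s yields
  11 windows, not the stated 12; the default uses 12 evenly spaced starts
  (step 20/11 s). A strict 2-s-step mode (11 distinct windows, last
  duplicated) is available behind a flag and logs the discrepancy.
- **Mode-vector reduction.** The stacked `(M·S)`-row mode is reduced to `M`
  channels by its first block row (the unshifted copy) — the
  minimal-assumption choice; block-averaged magnitude is an option.
- **Rescaling boundary.** Min-max rescaling is per image (per segment), not
  per epoch; together with the scale-invariance of `to_image` this makes the
  tensors invariant to global amplitude units.
- **CNN details not pinned by the architecture description.** Adam and
  cross-entropy (standard for a softmax head); conv stride 1 with same
  padding; ceil-mode pooling (required for 50 → 25 → 13 → 7 and
  12 → 6 → 3 → 2 to hold, flatten length 6272); no early stopping.
- **Partition remainders.** After a seeded shuffle, remainder subjects go to
  the earliest partitions ("equally sized" is impossible for 27 or 22).
- **Batch accuracy.** Epoch-weighted (cumulative over the batch's scored
  epochs); a fold-averaged alternative is trivially derivable from the
  prediction records.
- **Rounding.** Reported metrics use two decimals, half away from zero; the
  macro-total helper runs in exact decimal arithmetic so published cells
  reproduce bit-for-bit.
- **Class balancing.** For the combined (AD+FTD)/CN task, AD and FTD
  subjects keep epochs {0, 2, 4, 6, 8} — deterministic and spread across the
  recording.

## Numerical choices

- SVD: LAPACK `gesdd`, economy size; singular values below `10⁻¹² · σ_max`
  are truncated before inverting Σ (guards noise amplification), then capped
  at R.
- The feature-extraction path casts segments to float32 (~2× faster SVD on
  one core); the min-max rescaled images make single precision ample.
  `fit_dmd` itself defaults to float64 and all correctness tests run in
  float64.
- Eigenfrequencies use the principal log branch; signed frequencies are
  reported and the positive passband keeps one member of each conjugate
  pair.
- All-zero segments yield an explicit empty result (never NaNs); an empty
  passband yields an all-zero image with a logged warning.
- The CNN is a self-contained numpy implementation (im2col-style
  convolution, explicit backward passes, Adam); training is deterministic
  under a fixed seed. dB floors (10⁻²⁰) keep silent windows finite.

## Synthetic cohorts

`synthetic_eeg` emulates what the pipeline assumes about the data: 19
channels (10–20 montage) at 500 Hz, one stimulus interval per recording, a
15 Hz SSVEP term inside it, group-dependent band-limited components with
scalp topographies, and 1/f background noise (spectrally shaped white
noise, default exponent 1, RMS 3 µV). Default group signatures encode the
qualitative EO picture — posterior 10 Hz alpha in controls (4.5 µV, 3× the
AD-like amplitude), generalized 6 Hz theta elevation in the AD-like group,
anterior-temporal theta in the FTD-like group — and are configuration, not
code; a null cohort (identical components for every group) supports chance
calibration. The generator does not model biophysical head geometry,
artifacts, non-stationarity, or per-frequency stimulation schedules, so
passing end-to-end tests demonstrates that the pipeline recovers planted
spectral-topographic contrasts under subject-wise validation — not clinical
performance on real EEG.

## Problem sizes for the bundled experiments

The reduced end-to-end experiment (`run_synthetic_experiment`, also used by
the acceptance script) runs 6 subjects per group, 60-s recordings, 4 epochs
per subject, full-geometry features (19 ch, S = 48, R = 100, 4–40 Hz), one
batch × two folds × one repetition, and 16 CNN training epochs at batch
size 8 — sized for a single CPU core while keeping the full feature
geometry. The full 5 × 5 × 5
protocol is the same code path with the default arguments.

## Limitations

- The LNSO batch construction ("independent seeded re-partition") is one
  reasonable reading of a protocol whose batch-to-batch difference is not
  specified.
- Real-data accuracies require the external EO dataset and GPU-scale
  training; nothing here asserts them.
- The EDF writer is minimal (16-bit, 1-s records, integer sampling rates)
  and intended for fixtures and interchange, not clinical archiving.
- EEGLAB `.set` reading supports continuous (single-trial) MATLAB v5 files,
  with or without `.fdt` sidecars.
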