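# Methods

`eegdx` implements a two-stage subject classification analysis for
resting-state EEG case/control studies, together with a synthetic cohort
generator that makes every stage testable without access to recorded
human data.

## The analysis

**Preprocessing.** Continuous multichannel EEG (µV) passes through a
fixed sequence: 60 Hz notch filter and 0.5–50 Hz zero-phase FIR
band-pass (windowed design, transition bands chosen automatically by
MNE-Python's defaults — only the filter family and cutoffs are
prescribed), cropping to a uniform duration (240 s at full scale),
FastICA decomposition into 15 components with automatic removal of
components whose z-scored correlation against any EOG channel exceeds
3.0, common-average re-referencing, segmentation into 4-s epochs with
2-s overlap (onsets 0, 2, 4, …; `floor((T−L)/S)+1` fully contained
windows, i.e. 119 at 240 s), and rejection of any epoch whose
peak-to-peak amplitude exceeds 300 µV on any EEG channel. A separate
subject-level screening report flags subjects for exclusion when fewer
than half of their epochs would survive a stricter 250 µV criterion;
the 250 µV and 300 µV thresholds play distinct roles (subject exclusion
vs epoch rejection) and are kept separate. EOG channels inform ICA but
are excluded from epochs, rejection and all downstream features.

**Time-frequency features.** Each clean epoch is transformed per EEG
channel with complex Morlet wavelets at 40 logarithmically spaced
frequencies from 1 to 45 Hz, with frequency-proportional cycle counts
(`n_cycles = f / 2`). Power (squared magnitude) is decimated in time by
plain subsampling (every 16th sample, so 4096 samples at 1024 Hz become
256 time points), log-transformed as `10·log10(power + 1e-10)`, and
permuted to channels-last layout: one (40 × 256 × 68) image per epoch.
No baseline correction and no edge trimming are applied; at 1 Hz the
wavelet spans only half a cycle, so the lowest rows have poor frequency
resolution and wide cones of influence — kept as-is and documented.

**Epoch classifiers.** The primary model is a small 2-D CNN:
conv(16, (3,5)) → ReLU → batch norm → max-pool(2,2) → dropout(0.4),
a second identical block with 32 filters, then flatten → a single
sigmoid unit. Convolutions are unpadded ("valid"); the
activation-before-batch-norm order follows the narrated block order and
can be swapped with a flag. Training uses Adam (learning rate 0.001),
batch size 32, binary cross-entropy. The implementation is plain NumPy
(forward and backward passes, Adam), seeded end-to-end. The baseline is
an RBF-kernel SVM (C = 1, gamma = 'scale', inverse-frequency class
weights, Platt-scaled probabilities) on mean Welch band power per
channel in the five canonical bands (delta 1–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–45 Hz; 2-s Hann segments, 50% overlap — segment
shape is our choice, not prescribed). Feature order is channel-major,
band-minor.

**Leave-one-subject-out evaluation.** Each of the N subjects is held
out once; the classifier trains on all epochs of the other N−1
subjects. Standardization (elementwise z-scoring over flattened
features) is fitted on training epochs only and applied unchanged to
the held-out epochs. A subject's epoch probabilities are averaged into
one EEG score; the subject is predicted a case iff the score is
strictly greater than 0.5 (a tie goes to the control class). Per-fold
records keep every epoch probability so all reports, and the fusion
stage, are recomputable without retraining. Per-fold seeds are
`run_seed + fold_id`, making results independent of fold execution
order.

**Early stopping.** The number of training passes is not prescribed by
the protocol narrative, and monitoring the held-out fold leaks test
information into the stopping decision. The default
(`early_stop="internal_val"`) therefore carves a subject-stratified
validation split from the *training* subjects (≥1 subject, ~15%),
stops after `patience` stale passes and restores the best weights; the
leak-free property is enforced by a mutation-oracle test. A clearly
labeled `paper_faithful_test_monitor` mode monitors the held-out fold
instead, reproducing the historically common but flawed protocol for
comparability; `none` disables early stopping.

**Late fusion (stacking).** The subject-level EEG score is combined
with one clinical or demographic covariate at a time (DOCS, MIS, BAI,
BDI-II totals, age, sex, education) in a logistic regression
(ridge-penalized at unit strength — small-n boundaries are sensitive to
this, so it is configurable), evaluated under the identical LOSO
protocol: per fold, numeric inputs are z-scored and categorical inputs
one-hot encoded with parameters fitted on training rows only
(categories unseen in training map to all zeros). Subjects missing the
tested covariate are dropped listwise; the remaining N is reported.
Each augmented model's pooled AUC is labeled Improved / None / Worse
against the EEG-only baseline at two-decimal precision. The single
precision/recall/F1 triple reported per model is the macro average,
which coincides with the published convention for balanced groups.

**Metrics.** Confusion counts, per-class precision/recall/F1 with
support, accuracy, macro and support-weighted averages; zero
denominators report 0 with a flag. AUC is the pairwise concordance
probability (Mann–Whitney, ties ½) computed from ranks and verified
against an O(n²) enumeration oracle. Report rendering rounds half-even
at two decimals; internal values keep full precision.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
it is not a biophysical head model.

- **Background**: per-channel 1/f^β noise (β configurable in
  [0.5, 2], default 1) calibrated so the 0.5–45 Hz content has a 10 µV
  standard deviation. Calibrating on the analysis band rather than the
  raw signal stops sub-delta drift sampling noise from jointly
  anticorrelating all measured bands across subjects. An
  amplitude-modulated 10 Hz alpha rhythm loads on posterior channels
  (channels are ordered anterior → posterior).
- **Artifacts**: blink transients (300–500 ms half-period
  raised-cosine pulses, ~80–120 µV, frontal-dominant, amplified copies
  on the EOG channels; Poisson timing at a configurable rate) and
  sporadic high-amplitude 10 Hz noise bursts (one per selected 4-s
  span, guaranteed to exceed a configurable peak-to-peak threshold),
  with burst supports recorded as ground truth for rejection tests.
- **Group effects**: `band_power` multiplies theta-band power on a
  fixed fronto-central channel subset of cases by `1 + effect_size` —
  a classic spectral difference both classifiers can read.
  `spectrotemporal` injects identical cross-channel beta-chirp bursts
  (8→32 Hz sweep over ~0.6 s, one per 2-s segment, coherent across
  channels with an alternating ±1 zero-sum spatial pattern) into *both*
  groups, differing only in sweep direction: upward in cases, downward
  in controls. Because a downward chirp is the time reversal of an
  upward one, every time-averaged spectral feature — per-channel band
  power and its cross-channel covariance alike — is
  distribution-matched between groups by symmetry; the group signal is
  purely the orientation of the burst in the time-frequency plane.
  Per-channel per-band long-run power is additionally rescaled
  (iteratively, against a Welch oracle) to agree within 2%, and the
  generator raises if matching fails. Matching runs before artifact
  injection: artifacts are group-balanced nuisance processes, and
  compensating for to-be-rejected burst power would bake a persistent
  spectral offset into the clean epochs.
- **Covariates**: per-group normal draws with published descriptive
  means/SDs as defaults, clipped to instrument ranges (DOCS 0–80, MIS
  0–30, BAI/BDI-II 0–63) and rounded; sex and education are categorical
  draws with per-group probabilities. `covariate_separation` scales
  every between-group mean difference about its midpoint (1 reproduces
  the defaults, 0 removes group structure). Default missingness: age
  absent for one subject, MIS for two.
- Everything derives from one `SeedSequence`; identical configs give
  bit-identical cohorts.

What the generator does *not* emulate: volume conduction and realistic
topographies, non-stationary artifact regimes, heart/muscle artifacts,
inter-subject spectral diversity beyond random sampling, or any genuine
disease physiology. Passing tests therefore demonstrate that the
pipeline recovers the *kinds* of structure it claims to recover under
controlled conditions — not that the published human-data effect sizes
would replicate.

## Problem sizes

Full scale mirrors the study conditions: 68 EEG + 2 EOG channels,
1024 Hz, 240 s, 40 wavelet frequencies, up to 50 training passes. The
test suite and the acceptance script run the complete LOSO comparisons
on a scaled preset chosen to keep a laptop-CPU run comfortable while
preserving every stage and contrast: 20 subjects, 8 EEG + 2 EOG
channels, 256 Hz, 60 s (29 epochs per subject before rejection), 16
wavelet frequencies (64 time points after decimation), CNN capped at 30
passes with internal-validation early stopping (patience 10 — the
chirp-orientation cue emerges after roughly 15–20 passes at this size).
The full-scale path is exercised on a single subject to pin the shape
contract (119 epochs; 40 × 256 × 68 tensors).

## Numerical and degenerate-case conventions

- Zero-variance features are centered but not scaled (scale 1).
- A tied subject score of exactly 0.5 predicts the control class.
- AUC with all-equal scores is 0.5 by the tie convention; single-class
  truth is an error, never a default value.
- Morlet decimation is subsampling of the transform output, not
  low-pass-then-downsample; decimated output equals the full-resolution
  output at the same indices exactly.
- The filter stage measures its attenuation contracts on the central
  region of test tones, outside the zero-phase FIR edge transients.
- EDF round-trips quantize to 16 bits over each channel's own physical
  range; round-trip error is bounded by one digital step.

## Known limitations and caveats

- **Pessimistic null bias.** Under LOSO on a balanced cohort the
  held-out subject's class is always the training minority; Platt
  scaling then hands every held-out epoch a probability biased toward
  the *other* class, so subject-level AUC under a true null
  concentrates below 0.5 (often near 0) rather than around it. This is
  a property of the protocol, not a bug; tests assert the one-sided
  property (no spurious positive discrimination), and chance-level
  published figures slightly below 0.5 are consistent with it.
- The NumPy CNN is deterministic for a fixed seed and thread count but
  makes no cross-platform bitwise guarantees.
- FastICA on short test-scale recordings may emit convergence warnings;
  with few components the z-scored EOG-match statistic is bounded
  (max z ≈ (k−1)/√k), so small-montage configurations need a lower
  threshold than the full-scale default of 3.0 to remove anything.
- Epoch counts per subject differ after rejection, so pooled epoch-level
  metrics weight subjects unequally; subject-level metrics are primary.
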