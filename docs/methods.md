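# Methods

This note records the modeling choices behind `coughkit`, the defaults
and their rationale, and what the synthetic corpus does and does not
establish.

## Problem setting

The unit of modeling is a *sound event*: a short mono waveform at
44.1 kHz carrying one cough or one of 15 non-cough sound types, grouped
into three environment categories of five types each — animal (frog,
crow, cricket, rooster, dog), human-made (snoring, breathing, sneezing,
laughing, throat clearing) and hardware (washing machine, door knock,
vacuum cleaner, engine, air conditioner). All audio is resampled to
44.1 kHz (polyphase band-limited interpolation) before any processing;
multichannel input is averaged to mono.

Three detector schemes differ in what the training stage knows about
the environment:

- **unguided**: one-class ν-SVM (polynomial or RBF kernel) fitted to
  cough feature vectors only. The outlier rate ν upper-bounds the
  fraction of training margin errors; predictions map inliers to
  "cough". Default ν = 0.1 with a degree-2 polynomial kernel.
- **guided**: binary classifier; the non-cough class is composed from
  the five types of one category.
- **semi-guided**: binary classifier; the non-cough class mixes all 15
  types.

Class balance is enforced by the quota n′ = m/r: with m cough events
and r non-cough types, each type contributes ⌊m/r⌋ or ⌈m/r⌉ events
(the remainder types are a seeded uniform draw), sampled without
replacement. With m = 106: quotas 21–22 (guided) or 7–8 (semi-guided).

## Segmentation

Events are cut from clips by thresholding per-frame RMS energy: 25 ms
frames, 10 ms hop; a frame is active when its RMS exceeds 10% of the
clip's peak frame RMS (a *relative* threshold, so segmentation is
invariant to global gain). Active runs separated by sub-threshold gaps
shorter than 50 ms are merged; runs shorter than 100 ms are dropped.
The defaults keep typical cough events (0.36 ± 0.14 s) intact; all are
configurable. Onset resolution is one analysis frame. Cough events may
additionally be annotated with a phase count — the number of smoothed
energy-envelope maxima above a 15%-of-peak prominence floor, clamped to
the physiological range [2, 3] (explosive burst, intermediate phase,
voiced tail). The phase count is curation metadata only; it never
gates modeling.

## Augmentation

Every event is expanded to 18 instances: the original, 14 pitch shifts
(±0.5, ±1, ±1.5, ±2, ±2.5, ±3, ±3.5 semitones) and 3 time stretches
(rates 0.25, 0.5, 0.75). The operator set is fixed and deterministic:
no compounding (each variant applies exactly one operator) and no
randomized policies.

Conventions and implementation:

- *Stretch rate*: rate f slows playback for f < 1; output duration =
  input / f, so rate 0.25 quadruples the duration. Durations hold to
  within 2%.
- Both operators run on a phase vocoder (2048-sample Hann STFT, hop
  512, magnitude interpolation with heterodyned phase accumulation).
  A pitch shift of n semitones is a stretch by 2^(n/12) followed by
  FFT resampling back to the original length, which scales all
  spectral content by the same factor and preserves duration.
- The analysis is zero-padded by one FFT length on both sides: with
  modified phases the overlap-add edges no longer taper with the
  window, and unpadded reconstruction divides near-zero window sums
  into order-one samples.
- Phase-vocoder overlap-add is not energy-exact, so every variant's
  RMS is pinned to the original's; augmentation never introduces a
  gain change.

## Features

Each event maps to 120 values in fixed order: 40 MFCCs, 40 Δ, 40 Δ-Δ,
each mean-pooled over frames (`mfcc_01..40, d_01..40, dd_01..40` in
persisted CSVs). Analysis uses 2048-sample frames with 512-sample hop
at 44.1 kHz — a standard resolution at this rate — with a 40-band
triangular mel filterbank (HTK mel scale, 0 to Nyquist), log
compression floored at 1e-10, and an orthonormal DCT-II. Δ and Δ-Δ are
local linear regressions over a 9-frame window with edge replication,
so a stationary signal has identically zero delta blocks. Mean pooling
is the minimal-assumption aggregator for variable-length events; it
discards within-event dynamics beyond what the deltas capture.

Two selection procedures operate on training data only:

- *select-K-best* by ANOVA F score (both classes; used for binary
  schemes). The F statistic is the natural univariate score for
  signed real-valued features.
- *variance ranking* on cough-class rows only (one-class schemes see
  no negatives), smallest or largest K. The unguided default is the 70
  smallest-variance features; both directions are supported because
  the optimal direction is an empirical, kernel-dependent choice.

Ties break toward the lower feature index; both selectors are verified
against brute-force sorting oracles.

## Classifiers

Binary: decision tree (min_split 39–49, max_depth 10–20), random
forest and gradient boosting (100–300 estimators), Bernoulli naive
Bayes, k-NN (k 1–3, Euclidean; vote ties break toward cough), and SVMs
with polynomial kernel K(y_i, y_j) = (1 + γ y_iᵀy_j)^d (d 1–3, C 1–3,
coef0 = 1) or RBF kernel (γ ∈ {0.0001, 0.001, 0.01, 0.09}). The
Bernoulli model requires binary features; real-valued features are
thresholded at their per-feature training median, which keeps both
outcomes populated. One-class: ν-SVMs with the same two kernels,
ν ∈ {0.0001, 0.001, 0.01, 0.1}.

Numerical details: the one-class solver runs at tolerance 1e-8 —
at small ν the default tolerance leaves the margin under-optimized —
and predictions use a boundary tolerance of 1e-6 of the training
decision-value scale, so boundary support vectors (decision value ≈ 0
with solver-noise sign) count as inliers. Class 1 = cough everywhere;
scores for ROC analysis are decision-function values (or positive-class
probability where no decision function exists). AUC-ROC is reported
for binary detectors only.

Model names follow the compound convention "scheme–model-type
classifier–r (category)": `G-B RF-5 (M)`, `S-B RF-15`, `U-U SVM`.
Printed names carry the classifier family only, so parsing a name
recovers scheme, family, r and category but not the kernel.

## Protocol

The m original coughs are split 90/10 ten times (train size
⌈0.9·m⌉); the m composed non-coughs receive an independent split with
the same proportions each round. Augmentation attaches after
splitting, on each original event's own side only — train/test
exclusivity is enforced at the original-event level and verified by
waveform-hash intersection. Grid search evaluates every hyperparameter
combination (and K ∈ {10, …, 120} when sweeping selection) by mean
training-set ACC over the splits, with ties broken by mean F1, then
enumeration order. Metrics per split: ACC, FPR, FNR, precision,
recall, F1, AUC-ROC, with SEN = 1−FNR and SPE = 1−FPR exact
identities. On cough-only test sets (applicability testing against
external cough sources) accuracy is defined as the fraction predicted
cough — the recall of class 1 — and negative-class rates are undefined
(NaN). Aggregation is mean and ddof-1 std over exactly n_splits values.

One master seed feeds named, independent streams (corpus generation,
composition, splits, classifier initialization), so every run is
reproducible end-to-end.

## Synthetic corpus

The generator emulates the *structure* of a labeled environmental
corpus, not its sound: m = 106 coughs (broadband 400–6000 Hz bursts
with sharp attack, exponential decay, and 2–3 energy lobes separated
by near-silent gaps; durations N(0.36 s, 0.14 s) floored at 0.12 s)
and 22 events per non-cough type (durations N(1.0 s, 0.25 s), RMS
0.1 ± 3 dB jitter). The floor shifts the cough duration mean by
≈ 0.002 s — well inside the generator's statistical contract of ±0.03
on mean and sd.

The 15 noise archetypes are deliberate caricatures — harmonic stacks
with type-specific fundamentals (animal), band-limited breath noise
and burst trains (human-made), stationary low-frequency hums
(hardware) — constructed so category mean spectral centroids order
hardware < human-made < animal and categories are separable. That
construction is what makes cross-environment ordering properties
testable; it also means synthetic accuracies are near ceiling and say
nothing about accuracy on real recordings. What passing tests *do*
establish: the protocol arithmetic is exact, augmentation obeys its
duration/energy laws, selection matches brute force, leakage cannot
occur, ν behaves as specified, and a detector granted more environment
knowledge is never worse on this corpus (guided ≥ semi-guided ≥
unguided; matched environment ≥ mismatched).

Problem sizes in the test suite are scaled to the check at hand:
structural tests run on a 12-cough corpus; the scheme-ordering and
cross-environment checks run on the full default corpus over 5 master
seeds with 2 splits per seed; arithmetic checks use all 10 splits at
m = 106; the duration-realism check uses 1000 generator draws.

## Known limitations

- The MFCC frame aggregator (mean) and the mel/DCT variant are fixed
  choices; event descriptors are not invariant to large silence
  padding (silence frames enter the mean).
- The segmenter cannot separate overlapping events and does no
  denoising; its parameters are defaults chosen for cough-scale
  events, not fitted values.
- The phase vocoder is a straightforward magnitude-interpolation
  implementation; transient smearing at extreme stretches (rate 0.25)
  is audible but irrelevant to the feature-level contracts tested.
- Real-data adapters (reading external labeled datasets) stop at the
  directory/WAV convention `<sound_type>__<source_id>.wav`; no
  downloader or format zoo is included.
- Synthetic-corpus performance numbers are pipeline diagnostics only.
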