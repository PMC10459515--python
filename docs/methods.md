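# Methods

## Overview

`ulameeg` classifies short EEG epochs as ADHD-like or control from an
unusual image-based feature set: each epoch channel is turned into a
time-frequency image, the image is tiled into patches, and the only pixels
retained as features are those sitting where Sophie Germain primes fall on
an Ulam spiral laid over each patch. A ReliefF filter ranks these gray
tones and a kernel SVM is evaluated under stratified 10-fold
cross-validation. The pipeline stages, their assumptions, and the
parameters that matter are documented below.

## Preprocessing

Recordings are channel-major microvolt matrices with a sampling rate,
nominally 19 channels of the 10-20 montage at 128 Hz so that a 512-sample
epoch spans 4 s. Cleaning is two zero-phase IIR filters per channel:

- a 50 Hz notch (quality factor `q = 30`, i.e. a ~1.7 Hz wide notch) for
  power-line interference. The bandwidth is a package choice; any narrow
  setting leaves the physiological bands untouched.
- a 6th-order Butterworth low-pass at 60 Hz. At 128 Hz sampling the cutoff
  sits at 94% of Nyquist; if a configuration pushes it to or past Nyquist
  it is clamped to 0.99 x Nyquist with a warning rather than failing.

Both filters are applied forward-and-backward (`filtfilt`), so the net
phase response is zero and ridge positions in the scalogram are not
displaced. Zero-phase filtering is acausal; that is acceptable here
because classification is offline. The two filters commute as LTI systems;
the reflect padding used at the boundaries is not time-invariant, so the
commutation property holds to numerical precision only on interior
samples (verified in the tests).

Segmentation cuts non-overlapping, temporally ordered 512-sample windows
and discards the trailing remainder. Segments never span recordings, and
each inherits its recording's label. No artifact rejection, re-referencing
or resampling is performed.

## Time-frequency images

Each segment channel is transformed with an analytic generalized Morse
wavelet (GMW), frequency-domain form

    Psi(omega) ∝ omega^beta * exp(-omega^gamma),  omega > 0,

with symmetry `gamma = 3`, time-bandwidth product `P^2 = beta * gamma = 60`
(so `beta = 20`), peak-normalized to 2 at the peak angular frequency
`omega_p = (beta/gamma)^(1/gamma)`. The transform is computed by FFT:
`X(a, .) = ifft(fft(x) * Psi(a * omega))` over a geometric scale ladder
with 10 voices per octave (`a[i+1]/a[i] = 2^(1/10)`).

The automatic scale limits are a package rule: the smallest scale places
the wavelet peak at Nyquist; the largest is capped so that roughly two
wavelet time-domain standard deviations (`2 * a * sqrt(beta*gamma)`
samples) fit inside the window. For 512 samples at 128 Hz this spans about
1.2-64 Hz over 58 scales, covering all the classic EEG bands. The
convolution is circular, with no padding and no cone-of-influence
masking; boundary columns therefore wrap, and shift covariance of the
magnitude is exact.

The magnitude is min-max normalized per image (linear, no log transform),
resampled to 225 x 225 with bilinear interpolation, and quantized to 8-bit
gray by rounding half-up. A constant magnitude (e.g. an all-zero signal)
maps to an all-zero image. Rows are ordered high-frequency-first, the
standard scalogram orientation, which fixes patch indices. Rendering
normalized magnitude directly as gray skips the detour through a color
map followed by luminance conversion; direct gray is monotone in
magnitude and loses no information, whereas a colormap round-trip is
generally non-monotone. A colormap compatibility path was considered and
rejected as strictly worse for a gray-tone feature extractor.

## Ulam spiral / Sophie Germain mask

The n x n Ulam spiral (n odd) places 1 at the center and winds outward
counter-clockwise; this package fixes the first step to the right and the
second upward. The orientation convention is declared rather than
canonical — any fixed convention permutes coordinates without changing
the information content of the sampled set. Coordinates are 0-based
(row, col) with the origin top-left throughout.

The mask keeps every cell whose spiral value p is prime with 2p + 1 also
prime (Sophie Germain primes), ordered by ascending p, which fixes the
within-patch feature order. Counts for the supported patch sizes:

| n | 3 | 9 | 15 | 25 | 45 | 75 |
|---|---|---|----|----|----|----|
| SG primes <= n^2 | 3 | 8 | 15 | 27 | 61 | 127 |

Even n is rejected: there is no unambiguous center cell and no supported
configuration needs one.

## Feature vectors

A 225 x 225 image under a non-overlapping 15 x 15 window yields 225
patches; with 15 mask positions per patch and 19 channels the per-segment
feature vector has 19 * 225 * 15 = 64,125 gray tones. Ordering is
channel-major, then patch row-major, then ascending prime — arbitrary but
deterministic; any fixed ordering gives identical classifier behavior.
Supported patch sizes on a 225 image are the odd divisors {9, 15, 25, 45,
75}; whole-image mode treats the full image as one patch with a 225 x 225
spiral.

## ReliefF

Standard multi-neighbor ReliefF: weights start at zero; every instance is
visited once in index order (fully deterministic; a seeded subsample mode
exists for large datasets); for each visit the k = 5 nearest hits and per
miss-class k nearest misses are found; weights decrease by the mean
range-normalized |diff| to hits and increase by the class-prior-weighted
mean |diff| to misses, averaged over visits. Neighbor distances are
Euclidean on range-normalized features — the same normalization as the
diff terms — which makes the weights exactly invariant to positive
rescaling of any feature column. (Distances on raw gray tones were
considered since all features share the 0-255 scale, but per-feature
observed ranges differ, and raw-scale distances would break the
rescaling invariance.) Constant features score exactly zero. The
multiclass prior weighting is implemented but the pipeline is binary.

Two finite-sample facts worth knowing: (1) self-exclusion leaves one
fewer hit candidate than miss candidates, giving label-independent
features a small O(1/n) negative expected weight — visible at n ~ 25,
negligible by n ~ 80; (2) selecting features with ReliefF fitted on the
full dataset *before* cross-validation leaks label information into the
held-out folds and can drive CV accuracy to ~100% on pure noise at small
n. The evaluated classifier therefore refits ReliefF inside each training
fold; the whole-dataset weights are still computed and exported
(`weights.csv`) as a descriptive artifact.

Selection keeps the m = 7000 largest weights (descending, ties broken by
ascending index). When m exceeds the feature budget — as it does for the
reduced test profiles — all features are kept with a warning.

## Classification

Soft-margin SVM (minimize ||w||^2/2 + C sum(xi)), RBF kernel by default.
Evaluation is stratified 10-fold cross-validation over segments with, per
outer fold: z-score standardization fitted on the training fold,
fold-internal ReliefF selection (above), and an inner 5-fold grid search
maximizing accuracy over C in {0.1, 1, 10, 100} and RBF width in
{0.1, 1, 10}/d (d = selected feature count), then a refit on the full
training fold. ADHD is the positive class for sensitivity/precision/F1
(the clinical convention). Reported per metric: per-fold values, mean and
sample SD over folds, and pooled confusion counts.

Segment-wise folding is the default for comparability with the study
protocol it mirrors, but it allows segments of one subject on both sides
of a split, which inflates accuracy whenever subjects are individually
recognizable; `groups=` (CLI: `grouping: subject`) switches to
leakage-safe subject-wise folding via stratified group k-fold.

## Synthetic data

The generator emulates 19-channel, 128 Hz pediatric EEG as: 1/f^alpha
Gaussian background (alpha = 1, scale 3 microvolts SD) + one sinusoid per
band (delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz) with random
frequency and phase + white sensor noise (SD 1) + optional 50 Hz line
component. Channels are independent except for a shared common-mode
rhythm component (weight 0.3) mimicking inter-channel correlation.
Per-subject amplitudes carry 10% multiplicative jitter.

The class contrast is placed where the pediatric ADHD EEG literature
reports it: theta amplitude 6 vs 3 (ADHD-like vs control) and beta 1 vs
2, with delta and alpha equal at 4. The default dataset is 20 subjects
per class, 16 s each (4 segments per subject).

Named profiles: `separable` (the defaults above), `null` (identical class
distributions; 30 subjects per class with one 4 s segment each — one
segment per subject so segment-wise CV has no same-subject leakage under
the null, and enough instances that the pessimistic small-sample bias of
cross-validated accuracy, measured at ~0.40 mean accuracy with 24
instances, is negligible), and `tiny` (2 subjects per class, 2 segments
each, for I/O smoke tests).

What passing on this data does and does not show: the generator produces
stationary, sinusoid-plus-noise signals with a literature-motivated band
contrast. Success demonstrates that the full chain — filtering,
scalograms, prime-mask sampling, fold-internal selection, SVM — preserves
and detects a genuine oscillatory class difference, and the null profile
shows the chain does not manufacture one. It does not establish clinical
performance: real EEG is nonstationary, artifact-laden, and its class
differences are subtler than a 2:1 amplitude ratio.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end profiles at
two scales chosen by the package: the full reference rendering
(225 x 225 images, 64,125 features, m = 7000) for the separable run, and
a reduced rendering (45 x 45 images, 2,565 features, m = 500) for the
tiny-fixture and repeated null runs, where the patch geometry and every
algorithmic step are identical and only the image resolution and feature
budget shrink. Tie-breaks (feature selection, argmax) are resolved by
ascending index via stable sorts; all randomness flows through explicit
seeds; reruns with the same configuration are bit-identical, and a
config-hash cache reuses unchanged stages.

## Known limitations

- The scale-limit rule for the CWT is a documented stand-in for an
  "automatic" convention that has no published formula.
- No cone of influence: wrap-around energy contaminates boundary columns
  at large scales.
- No artifact model (blinks, muscle) in the generator, and no artifact
  rejection in preprocessing.
- Patch-feature rotation invariance is untested and not claimed.
- EDF reading requires `mne`; without an EDF writer in the environment the
  EDF path is exercised only for its error handling.
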