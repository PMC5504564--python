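# Methods

This note records the models, parameter choices and numerical conventions
behind `semgrecal`, and what the synthetic studies can and cannot show.

## Feature pipeline

Segments are 200 ms windows (400 samples at 2 kHz) advanced by 100 ms;
the count is `floor((N − 400)/200) + 1`. A window containing a label change
is labelled by the per-sample mode, ties going to the earlier-occurring
label (any fixed rule works; this one is deterministic and favours the
movement already in progress).

The spectrogram is the plain magnitude of the short-time DFT — Hamming
taper, 256-point FFT, 184-point overlap, no window-sum or density scaling —
giving 129 frequencies × 3 time bins per channel. Only the first 95
frequency bins are kept. At 2 kHz with a 256-point FFT the bin spacing is
7.8125 Hz, so bins 0–94 span 0–734.375 Hz; the cut keeps the band where
surface-EMG energy concentrates (below ~700 Hz). Because the subsequent
normalization is affine per channel, the absence of scaling in the
magnitude is immaterial downstream.

Normalization maps each channel's intensities to [0, 1] using the 1st and
99th percentiles of the *initial training set* as minimum and maximum,
clipping values outside the range; a degenerate channel (p1 = p99) maps to
0. PCA is fitted per channel on the vectorized 95 × 3 arrays (285 features)
and the first 25 components are kept per channel (300 scores per segment).
Component sign is fixed by making each component's largest-magnitude
loading positive, so the basis is reproducible across numerically
equivalent fits.

Both the percentiles and the PCA basis are fitted once on the initial
training session and then frozen. Refitting them at recalibration would
silently move the feature space under the warm-started network; freezing
keeps every session's features in the same coordinate system, which is what
makes fine-tuning meaningful.

## Center-out grid

The 25 per-channel scores are placed on a 5 × 5 grid by sorting cells by
Euclidean distance from the center (ascending), ties broken clockwise
starting from the cell directly above the center. Rank 1 lands at the
center and ranks 22–25 at the corners, so every position of the 4 × 4
convolution filter covers the dominant components. The layout is a pure
permutation (exactly invertible) and is pluggable; any layout satisfying
the center/corner constraints is admissible, and the choice only has to be
held fixed between training and inference.

## Classifier

One valid cross-correlation layer (4 × 4 filter, 64 filters by default,
summing the 12 input channels), two fully connected ReLU layers (800
neurons each by default) with inverted dropout at rate 0.5, and a softmax
output. Training is plain mini-batch SGD (defaults: learning rate 0.01,
batch 64, 60 epochs from scratch, 15 epochs for warm-started fine-tuning);
all of these are configurable and the desk-scale studies use a smaller
network (8 filters, 128 neurons, learning rate 0.05) that trains in
seconds on one CPU. Backpropagation is hand-written and verified against
central finite differences (relative tolerance 1e-4) in the test suite.
Initialization is He-scaled Gaussian from an explicit seed; batch order and
dropout masks come from the same generator, so training is bit-reproducible.
Inverted dropout needs no rescaling at inference, and inference never
applies dropout. For ablations the convolutional layer can be replaced by a
dense layer of equal output width (`use_conv=False`) and dropout disabled
(`dropout_rate=0`).

A non-finite training loss raises a divergence error naming the learning
rate; note that an over-large step can also silently kill all ReLUs and
flatline instead, which is reported by accuracy, not by an exception.

## Label correction

Both corrections use a truncated window at sequence boundaries (the
available neighbours are used; edge segments are not discarded). Mode ties
keep the original label when it is among the tied modes, otherwise the
smallest class id — deterministic and conservative. Median-probability
argmax ties resolve to the smallest class id. For streams whose true-label
runs are at least 2x + 1 segments, an interior segment is corrected
correctly exactly when the majority of its window is correct, so with iid
error rate p the corrected accuracy is the binomial tail
`P[Bin(2x+1, 1−p) ≥ x+1]` (≈ 0.923 for x = 10, p = 0.35); the test suite
verifies the implementation against this closed form. Corrected — not raw —
labels are fed back in both recalibration scenarios.

## Synthetic study generator

Movement activity is modelled as 4th-order Butterworth band-pass-filtered
Gaussian noise with a class-specific center frequency and bandwidth, scaled
by per-class per-channel amplitude weights, shaped by a trapezoidal
envelope with 100 ms ramps, plus white sensor noise; rest is sensor noise
only. Defaults mirror a standard acquisition protocol: 12 channels at
2000 Hz, 6 repetitions per movement, 3 s rest between movements, 5 s
movements (movement length in public databases varies and is configurable).
Class center frequencies default to an even spread over 80–450 Hz with
120 Hz bandwidth, and each class emphasizes a different smooth "bump" of
channels — the two cues (spectral content and spatial pattern) that real
movement classes differ by.

Session-to-session drift is the s-fold composition of a per-session
transform with three canonical components: a rotation applied pairwise to
adjacent channels (electrode shift / crosstalk), a multiplicative
per-channel gain, and a single-sideband spectral shift (Hilbert-transform
modulation). The composition is evaluated in closed form (angle, gain
exponent and shift all scale linearly with the session index), so drift is
cumulative and monotone by construction.

### Study conditions for the drifting experiment

The desk-scale experiment (`pipeline.StudyConfig`) uses 5 movement classes
plus rest, sensor noise 0.4, mixing 0.15 rad/session and gain ×1.08/session
with no spectral shift, a small network (8 filters, 128 neurons), and
median-probability correction with x = 10. Session 0 (repetition 1,
undrifted) is the initial training set; sessions 1–5 are tested in order.

Two findings from designing these conditions are worth recording. First,
the qualitative decay of the unrecalibrated classifier is robust to the
drift mechanism, but the *relative ordering* of the two recalibration
scenarios is not: under spectral-shift drift, when classes are cued by
their spectra, old sessions become label-contradictory (class c drifted by
several sessions resembles class c+1 undrifted), and accumulating them
actively hurts — Last-Only then beats All-Session. Under coherent spatial
drift (mixing + gain) the classes move together without crossing, old
sessions act as augmentation, and All-Session edges ahead, matching what
multi-session sEMG studies report. The default conditions therefore use
spatial drift. Second, even there the All-Session-vs-Last-Only margin is
small (a fraction of a percentage point averaged over ten seeds), which is
consistent with the small median difference such studies report between the
two; the decisive contrast is recalibrated versus not (≈ +10 percentage
points over sessions II–V under these conditions).

### What the generator does not model

No motor-unit action potentials, force levels, fatigue dynamics,
within-session drift, or label noise in the "ground truth"; drift is
deterministic rather than stochastic, and sessions are statistically
stationary inside. Passing the synthetic studies therefore demonstrates
that the adaptation machinery behaves as designed under controlled
non-stationarity — not that a particular accuracy will be attained on real
recordings, whose absolute numbers depend on the subject pool and protocol.

## Problem sizes and runtimes

The default test run uses: ≤ 200-length random streams (× ≥ 1000) for the
correction oracles; 10 seeds × 3 scenarios × 6 sessions of ~400 segments
for the drifting study (~1 minute); 300 streams of 200 segments for the
binomial-tail check; a ~100-parameter model for the finite-difference
gradient check. `scripts/acceptance.py` repeats the drifting study over
5 seeds and finishes in a few minutes on one CPU.

## Known limitations

- The center-out layout is one consistent instantiation of the
  center/corner constraints; alternative spirals are configurable but not
  learned.
- The HDF5 feature container stores one object per file; there is no
  multi-subject database management.
- The classifier interface is pluggable in principle (the protocol only
  needs `train`/`fine_tune`/`predict_proba`), but only the CNN is provided;
  margin-based classifiers without warm-start would need from-scratch
  retraining at each recalibration (available via configuration).
- Plain SGD is deliberate (matching the simplest published practice), so
  learning rates need to be chosen per problem scale; divergence raises,
  but dead-ReLU flatlining does not.
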