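# Methods

This note documents the models and procedures implemented in `pcg_chd`,
the defaults chosen where the method itself leaves freedom, and what the
synthetic test bed does and does not establish.

## Signal representation and I/O

Recordings are mono float arrays in [−1, 1] with an explicit sampling rate.
Integer WAV samples are normalized by the *full-scale magnitude of their
bit depth* (16-bit ÷ 32768), never by the per-file peak: the EMD envelopes
and the LTP threshold φ operate on absolute amplitudes, so per-file peak
normalization would silently rescale features between recordings. Writing
quantizes by rounding to 16-bit PCM (+1.0 → 32767), bounding the
write/read round-trip error by 2⁻¹⁵. Multi-channel files are rejected by
default (auscultation at a single site produces mono audio); an explicit
`channel_mode="mean"` averages channels after normalization. Reads never
resample; `resample()` (polyphase) is a separate, deliberate step.

## EMD denoising

Sifting follows the standard scheme: locate strict local extrema (a
plateau counts once, at its midpoint), interpolate maxima and minima with
cubic splines to form upper/lower envelopes, subtract the envelope mean,
repeat. Two choices the scheme itself does not fix:

* **Sift stop.** The Cauchy criterion SD = Σ(y_prev − y_new)² / Σ y_prev²
  < 0.2, capped at 100 iterations per mode. 0.2 is the canonical choice;
  tighter thresholds sharpen the IMF symmetry property but over-sift,
  bleeding energy between modes. Consequence: IMFs are *approximately*
  symmetric — for broadband-noise modes the extrema/zero-crossing counts
  agree to within a few percent rather than exactly, which the test suite
  asserts at that honest tolerance (smooth oscillatory modes satisfy the
  strict ±1 balance).
* **Boundaries.** The two extrema nearest each end are mirrored about the
  end sample before spline fitting; this anchors the envelopes beyond the
  signal and suppresses the end swings that plain extrapolation produces.

Decomposition stops when the residual has fewer than two maxima or two
minima, or at `max_imfs` (default 12, a guard against over-decomposition
of long recordings). Completeness — IMFs plus residual reconstruct the
input — holds to round-off (~1e−16 relative L2, asserted at 1e−8) because
each stage subtracts exactly what it extracts.

Denoising keeps IMFs 2..N−2 (1-based). With N < 4 the kept range is empty;
the default is to raise, with an `on_shallow: passthrough` escape hatch
that returns the signal unchanged. IMF selection is fixed-rule, not
data-driven.

## 1D-LTP descriptor

Windows of 2·half_width+1 samples (default 9, i.e. 8 neighbors) slide one
sample at a time over fully interior positions; no padding, so the code
stream is `len(signal) − 2·half_width` long. Neighbors are enumerated left
frame nearest-to-farthest then right frame — irrelevant once histogrammed,
but fixed for reproducibility of the raw codes.

* **φ** defaults to 0.1 × the standard deviation of the (denoised) signal,
  recomputed per recording. A relative threshold keeps the coding
  meaningful across recordings of different loudness; an absolute mode is
  available when comparability of raw codes matters. At the boundary case
  φ = 0 the +1/−1 conditions overlap at equality; −1 wins, keeping the
  upper/lower patterns mutually exclusive by construction.
* **Weights** default to the standard binary convention 2^(p−1) (codes
  0..255 for 8 neighbors). A `literal` convention 2^p (codes 0..510) is
  exposed behind a flag; since the descriptor is a histogram over the full
  attainable code range, the two conventions yield the same descriptor up
  to bin-edge effects.
* **Descriptor.** Each of the upper and lower code streams is reduced to a
  10-bin equal-width normalized histogram over the full code range, giving
  the 20-value descriptor (10 + 10). Normalization makes the descriptor
  invariant to recording duration; binning over the fixed attainable range
  (rather than the observed range) makes bins comparable across
  recordings.

Adding a constant to the signal leaves every code unchanged (θ shifts with
the window center), so the descriptor is amplitude-shift invariant.

## MFCC descriptor

Per frame: pre-emphasis y[t] = x[t] − 0.97·x[t−1] (first sample kept),
Hamming window, magnitude-squared FFT (size = next power of two ≥ window,
2048 for the 1323-sample window at 44.1 kHz), a 26-filter triangular mel
filterbank between 0 Hz and Nyquist with centers equally spaced on the mel
axis, log(energy + 1e−12) — the ε floor keeps silent frames finite — and
an orthonormal DCT-II. Frames are 30 ms with a 10 ms hop and lie fully
inside the signal.

The recording-level descriptor is the per-coefficient arithmetic mean over
frames of the first 13 coefficients including c0 (`include_c0` is
configurable; c0 is the only coefficient affected by a pure gain change,
which the tests verify). 26 filters and α = 0.97 are the common speech
defaults; filterbank size, pooling rule and c0 inclusion are configuration
choices the method's printed dimension (13) does not constrain.

The filterbank constructor rejects configurations whose adjacent filter
centers collapse onto one FFT bin (this bites below ~3 kHz sampling with
26 filters and a power-of-two FFT of a 30 ms window; raise `fft_size` or
lower `n_filters`).

## Feature fusion and SVM evaluation

The fused vector is MFCC (13) then LTP (20), a fixed 1×33 order. Four SVM
kernels are supported, all one-vs-one and C = 1 by default, with features
z-scored using training-fold statistics only. Kernel scale s enters by
dividing the inputs, so Gaussian = exp(−‖x−z‖²/s²) and polynomial =
(1 + x·z/s²)^degree with degree 2 (quadratic) or 3 (cubic). "Automatic"
scale resolves to √d (d = number of features, i.e. √33 ≈ 5.74 after
standardization) — a deterministic stand-in for subsampled
median-distance heuristics, chosen so repeated runs are bit-reproducible.

Evaluation: stratified k-fold (default k = 10), repeated (default 100)
with folds reshuffled per repeat by `seed + repeat_index`; per repeat the
held-out predictions are pooled into one confusion matrix and scored;
reported metrics are means over repeats. If the smallest class has fewer
than k members, k is reduced to that count with a warning so
stratification stays exact. Metrics: accuracy = (TP+TN)/total ×100,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), error = 100 − accuracy. For K > 2 classes the
class-conditional metrics are one-vs-rest per class and macro-averaged
(the reduction is otherwise underdetermined); accuracy stays
trace/total. A 0/0 ratio yields NaN (serialized as null), never an
exception. The binary screening task relabels ASD and VSD as "abnormal".

## Synthetic phonocardiograms

Each recording is a train of cardiac cycles at 75 ± 5 bpm (uniform jitter
per cycle). S1 (40 Hz, 120 ms, amplitude 1.0) sits at the cycle start, S2
(60 Hz, 100 ms, 0.8) at 35% of the cycle; both are Gaussian-enveloped
sinusoids with random phase. Class signatures:

* **VSD** — holosystolic murmur: 80–180 Hz band-limited noise, flat
  envelope spanning the S1→S2 interval, amplitude 0.5 relative to S1. A
  septal jet lasts all of systole and is harsh, hence flat and relatively
  loud.
* **ASD** — mid-systolic crescendo–decrescendo (Hann²) flow murmur,
  60–120 Hz at 0.35 relative amplitude, plus the fixed split S2: two
  0.7-amplitude sub-bursts 50 ms apart.

White noise is added at 10 dB SNR by default and the result
peak-normalized to 0.9. Murmur amplitudes and bands are stylized but sit
inside the 20–200 Hz heart-sound band so the IMF-rejection denoiser
treats them like real murmurs.

Determinism: one recording is fully determined by its seed; datasets
derive a child seed per recording from (dataset seed, index), so a
recording's content is independent of how many others are generated.

**What this test bed shows and does not show.** Passing the simulated
study (≥ 90% cross-validated accuracy at 10 dB SNR, chance-level accuracy
under label permutation) demonstrates that the pipeline's stages compose
correctly and that the descriptors separate the class signatures they were
designed to capture. It does *not* estimate clinical performance: real
murmurs vary in intensity and band with defect size and subject, real
recordings contain respiration, movement and sensor artifacts, and
recordings from one subject are correlated — none of which the generator
models. The simulated classes are, by construction, cleaner than hospital
data; simulated accuracies near 100% should be read as a pipeline
integrity check, not a clinical claim.

## Problem sizes used in tests and the acceptance script

Simulated studies run at a reduced sampling rate of 4 kHz; every window
constant in the pipeline is specified in milliseconds, so nothing in the
chain depends on the 44.1 kHz default (which remains the faithful setting
for real recordings, verified by the 1323-sample window constant). The
packaged study uses 60 recordings per class, 5 s each; cross-validation
uses 10 repeats for the accuracy estimate and 100 repeats for the
permutation null, whose variance is what the ±5-point band is judged
against.

## Known limitations

* IMF selection for denoising is a fixed index rule (2..N−2), not adaptive;
  at low sampling rates or short durations N can drop below 4, where the
  rule degenerates (error or passthrough, by configuration).
* Sifting with SD < 0.2 leaves approximate IMFs (see above).
* The MATLAB-style "automatic" kernel scale is approximated by √d rather
  than a data-driven heuristic; with standardized features the two are
  close but not identical.
* The generator does not model subject-level correlation, so
  cross-validation folds are exchangeable at the recording level only.
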