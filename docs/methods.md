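# Methods

`cortimbre` implements a two-stage model of auditory cortical processing
and uses its output for musical-instrument recognition and for predicting
perceptual timbre dissimilarity.  This note records the model equations as
implemented, the numerical conventions, the design choices that were
genuinely open, and what the synthetic benchmark does and does not show.

## Early stage: waveform → auditory spectrogram

The input waveform (resampled to 16 kHz, pre-emphasized with the FIR
`[1, −0.97]`) passes through:

1. **Cochlear filterbank.** 128 constant-Q bandpass filters with
   characteristic frequencies `CF_k = 180 · 2^(k·5.3/127)` Hz, k = 0…127 —
   24 channels/octave over 5.3 octaves.  Filters are complex order-4
   gammatones `t³ e^(−2πbt) e^(i2πft)`; the quality factor (CF over 3-dB
   bandwidth) defaults to 8, a compromise between channel selectivity and
   ringing time, and is configurable.
2. **Hair-cell stage.** A temporal first difference of the complex channel
   signal (AC-coupled high-pass), rectification realized as the
   analytic-signal magnitude, an optional compressive `tanh` (off by
   default so the stage is positively homogeneous and the scaling
   invariants are testable), then a one-pole low-pass at 2 kHz.  Taking the
   magnitude of the analytic signal rather than half-wave rectifying the
   real part makes the representation exactly invariant to a sign flip of
   the waveform; classically the two differ only by a factor and a small
   amount of carrier ripple.
3. **Lateral inhibition.** First difference across adjacent channels
   followed by half-wave rectification — the standard feed-forward
   realization of a lateral inhibitory network, which sharpens the
   tonotopic profile.
4. **Midbrain integration.** Leaky integration with τ = 4 ms, sampled into
   frames.

The spectrogram frame rate defaults to **500 Hz**.  A lower display rate is
common, but the fastest temporal-modulation filter in the cortical stage is
tuned to 128 Hz, and filtering at 250 frames/s would place it above the
frame Nyquist; emitting 500-Hz frames keeps the spectrogram, the
modulation filtering, and the dense-convolution oracle on a single time
grid.

## Cortical stage: modulation filterbank

Each cortical filter is a directional spectro-temporal wavelet tuned
(Q ≈ 1) to a rate ω (temporal modulation, Hz) and a scale Ω (spectral
modulation, cycles/octave):

- temporal seed `h_t(τ) = τ² e^(−3.5τ) sin(2πτ)`, dilated by ω;
- spectral seed: Ricker/Gabor `(1 − u²) e^(−u²/2)` on the octave axis,
  dilated by Ω.

The seed arguments are calibrated (a measured factor ≈ 1.005 for the
temporal seed, `2π/√2` inside the spectral seed) so that each filter's peak
Fourier response falls exactly at its nominal (ω, Ω): with the raw seeds,
a filter labelled Ω would actually peak near 0.22 Ω, and "nearest-filter"
statements would be meaningless.  Analytic (one-sided) versions of both
kernels are produced by the Hilbert transform; the downward-selective
filter is the product of the two analytic kernels, the upward filter uses
the conjugated temporal kernel.  Rates are
[4.0, 5.7, 8.0, 11.3, 16.0, 22.6, 32.0, 45.3, 64.0, 90.5, 128.0] Hz, each
upward and downward; scales are
[0.25, 0.35, 0.50, 0.71, 1.00, 1.41, 2.00, 2.83, 4.00, 5.66, 8.00] c/o.
Applied at all 128 channels the bank spans 128 × 22 × 11 = 30,976 filters.

**Convolution conventions.**  The joint transform convolves causally and
linearly along time (zero-padded FFT; the response is read over the note's
frames) and circularly along the 128-channel tonotopic axis, where the
spectral kernel is defined on the wrapped octave grid.  Only response
magnitudes are kept (zero-phase reading), averaged over the note duration,
giving the 128×22×11 tensor per note.  A dense direct-summation
convolution serves as the independent oracle in the tests.

**Control variants.**
- *Separable*: independent 1-D rate filtering (per channel, along time)
  and scale filtering (per frame, along frequency); magnitudes
  time-averaged and stacked to 22·128 + 11·128 = 4,224 dims.  The 1-D
  transforms are circular on the note's own frame/channel grids with
  transfer functions that are exactly one-sided in the DFT domain.  This
  makes the features exactly phase-blind — hence exactly direction-blind —
  for probe ripples completing integer temporal cycles over the note,
  which is the designed property of a separable analysis (it cannot carry
  orientation).  The upward and downward halves of the rate block use
  conjugate kernels and are numerically identical for real input.
- *Global*: rate and scale marginals of the separable output summed over
  frequency (22 + 11 = 33 dims) — akin to a 2-D Fourier summary of the
  spectrogram.
- *Undersampled*: the joint transform on a 2× frequency-downsampled
  spectrogram with 5 rates × 2 directions and 6 scales
  (64 × 10 × 6 = 3,840 dims).
- *Spectrum*: the time-averaged auditory spectrogram (128 dims).

**Measured receptive fields.**  STRF records (lag × frequency weight
matrices with a bootstrap SNR) are aligned to the model grid by stretching
their octave span onto the 128-channel/5.3-octave axis and resampling lags
to the frame period (cubic interpolation); records with SNR < 2 are
discarded.  Each STRF is convolved with the spectrogram across the
tonotopic axis ("same" centered along frequency, causal along time), the
absolute response is time-averaged per channel, and the per-record
128-vectors are stacked — 1,110 records give 142,080 dims.  The synthetic
bank emulates the physiological population: Gabor receptive fields with
rates 4–24 Hz, scales up to 1.4 peaks/octave, random direction, SNR
uniform on [0.5, 10].

## Feature reduction

Tensor SVD: the stacked note tensors are unfolded along each mode
(frequency, rate, scale), each unfolding is decomposed by SVD, and the
leading components per mode are kept — 21 eigenfrequencies × 4 eigenrates
× 5 eigenscales = 420 features.  Variance retained is reported overall
(projected energy over total energy); per-mode spectra are stored.  Bases
are sign-fixed (largest-magnitude entry positive) for reproducibility.
Mean-centering is off by default; the decision-space analysis switches it
on so that the class-contrast direction loads on the leading components
rather than on the grand-mean profile.  During cross-validation the
projection is fit on the training folds only (an information-leak guard;
fitting on all data is available as a switch).

## Classification

One-vs-one soft-margin SVMs with the Gaussian kernel
`K(x,y) = exp(−‖x−y‖²/(2σ²))` or a linear kernel; a test sample takes the
majority vote of all pairwise classifiers, ties broken by summed signed
decision values, then lexical order.  A single (σ, C) pair is selected by
grid search — σ over 10 log-spaced values spanning the 5th–95th percentile
of pairwise distances, C ∈ {0.1, 1, 10, 100} — on a held-out split of a
subset of the first fold's training data, and reused across all pairs and
folds.  Grid-search ties prefer the larger σ at its smallest tied C.
Evaluation is stratified 10-fold cross-validation (90% train / 10% test).

The benchmark classifiers run on the features' natural scale.
Per-dimension standardization of the 420 tensor-SVD features (available as
a switch, and the default for generic use of `cross_validate`) equalizes
noise components, which measurably degrades the Gaussian kernel relative
to the linear one; the tensor SVD already orders components by variance
and the classifier is applied directly to them.

## Decision-space analysis

For each cross-class instrument pair, the support vectors of the pairwise
Gaussian classifier are treated as samples from two distributions in the
420-dim reduced space.  Per dimension, 100-bin histograms over shared
min–max edges estimate the densities; the symmetric KL divergence
`KL(p‖q) + KL(q‖p)` is computed over bins where both are non-zero (an
add-ε smoothed variant is available and agrees within ~10% on
non-degenerate inputs); the 420 values are arranged over (eigenfrequency,
eigenrate, eigenscale) and averaged across instrument pairs within each
class pair (mean by default, median available).  Wilcoxon rank-sum and
Kruskal–Wallis comparisons are exposed as thin wrappers over SciPy.

The shipped experiment runs this analysis on the 11-instrument benchmark:
the one-vs-one Gaussian SVM is trained at the instrument level on
mean-centered tensor-SVD features, divergences are pooled over the three
class pairs (winds–strings, winds–percussions, strings–percussions), and
the eigenrate marginal of the pooled tensor is summarized by the share
carried by the two leading eigenrates.  Centering matters here: without
it the first component of every mode is the grand-mean profile and the
class contrasts load lower.  A two-class contrast (one percussive vs one
sustained archetype) is *not* a usable probe at this scale — with two
balanced classes the contrast direction is itself the dominant variance
direction, so the per-dimension, scale-invariant divergence relocates to
later eigenrates; the diversity of the full benchmark is what shapes the
eigenrate basis the way the analysis assumes.

## Perceptual-similarity kernel learning

Instrument profiles are the mean feature vectors across notes.  The
weighted kernel `K_β(x,y) = exp(−Σ_d β_d (x_d−y_d)²)` induces the distance
`d_K = √(2 − 2K_β)` (the canonical RKHS metric for a normalized kernel);
the objective is the Pearson correlation between `{d_K(x̄_i, x̄_j)}` and the
human (or simulated) dissimilarities `{D(i,j)}` over the strict upper
triangle.  Human matrices are averaged over presentation orders (and
notes) before fitting.

β is optimized in log-parameters `β_d = e^{b_d}` (positivity by
construction), initialized uniformly at `1/(N · median pairwise squared
difference)`.  The default optimizer takes per-coordinate
moment-normalized ascent steps (Adam-style, step 0.05, 2,000 iterations):
plain fixed-step ascent stalls on uninformative dimensions, because the
log-space gradient of a vanishing weight vanishes with it, so weights that
should decay to zero never do; per-coordinate normalization lets them
decay at a uniform rate while the informative weights converge.  A
monotone backtracking fixed-step variant (`method="backtracking"`, stop at
|ΔJ| < 1e-6) is retained, and the analytic gradient is verified against
central finite differences.

## Synthetic benchmark: what it emulates

No recorded instrument audio, measured receptive fields, or human ratings
ship with the package; the `synth` module generates all inputs.

- **Notes** are additive: harmonics of f0 with a spectral-envelope gain
  law, a common amplitude envelope (linear attack, exponential decay to a
  sustain level), sinusoidal frequency vibrato and amplitude shimmer, and
  optional inharmonic partial jitter.  Stimuli are truncated to 250 ms
  with a 50-ms raised-cosine offset ramp (onset preserved) and RMS
  normalized; the digital RMS reference (0.05) is arbitrary since
  presentation level in an experiment is an acoustic calibration.
- **The 11-instrument benchmark is built to differ temporally.**  All
  archetypes share one register (f0 around 220 Hz, ±8 semitones per note)
  and the same mean spectral slope, and body resonances are *redrawn per
  note*; instrument identity is carried by attack (3 ms–160 ms), decay and
  sustain, vibrato rate/depth (strings), shimmer rate/depth (winds), and
  tremolo/inharmonicity (percussion), with style (normal/staccato/
  espressivo) and dynamic variation per note.  This is the regime in which
  a spectral-profile classifier must fail and a temporally informed one
  can succeed; it deliberately removes the stable spectral cues that real
  instruments also provide, so absolute accuracies are far below those
  reachable on recorded notes and only the *ordering* across
  representations is meaningful.
- **Simulated observers** rate dissimilarity as a monotone [0,1] rescaling
  of ground-truth generative-parameter distances plus clipped Gaussian
  slider noise, per presentation order.  The kernel-recovery experiment
  uses 100 simulated sound sources: with only ~a dozen, the 4,950→78 drop
  in pair count makes the 420-weight correlation objective unidentifiable
  (any optimizer reaches r ≈ 1 by overfitting) and weight recovery is not
  assessable.  What passing shows is that the optimizer recovers a known
  generating metric under rating noise — not that human timbre judgments
  are two-dimensional.
- **The decision-space analysis** reuses the benchmark dataset (see
  above), so its class structure — percussions vs strings vs winds,
  distinguished by temporal envelope and modulation — is exactly the
  regime in which divergence between classes should concentrate on the
  temporal (eigenrate) components.

## Numerical choices and degenerate inputs

- Temporal kernels are truncated where the seed envelope falls below
  ~1e-5 of its peak (τ ≤ 6); cochlear IRs below 1e-5 of peak.
- FFT sizes use `next_fast_len`; the joint transform holds the channel
  DFT fixed while slicing valid time frames before the per-scale inverse
  transform, which is what makes the 242-filter bank affordable.
- Histogram edges guard their extreme bins with `nextafter` so pooled
  min/max samples always land inside.
- Attack time: the −12 dB point is the first upward crossing of the
  smoothed analytic envelope; the −40 dB point is the last sub-threshold
  instant before it (keeps the measurement on the rise segment, away from
  analytic-signal leakage into leading silence); the rise time is clamped
  to one sample period before the log.
- Spectral centroid compresses channel *energy* (profile squared) with
  exponent 0.3.  Pure-tone centroids sit 2–3 channels (~0.1 octave) below
  the tone channel because compression keeps the asymmetric cochlear
  skirts in play; this is a property of the descriptor, not an error.
- Zero spectrograms, silent waveforms, constant dissimilarity matrices,
  sub-250-ms stimuli, misaligned STRF grids and undersized classes all
  raise informative errors rather than propagating NaNs.

## Problem sizes

The shipped experiments run on one CPU core: the classification benchmark
uses 11 instruments × 100 notes with 10-fold cross-validation; the ripple
suite probes 24 (rate, scale, direction) combinations at 1-s duration; the
decision-space analysis shares the benchmark dataset and features; kernel
recovery uses 100 sources × 420 dims with 20 simulated raters.  These sizes were chosen so
the full suite completes in well under half an hour while every qualitative
contrast remains statistically clear.

## Known limitations

- The synthetic notes lack attack noise/transient inharmonicity, room
  acoustics, and performer variability; absolute accuracies and
  correlations are not comparable to values obtained on recorded corpora.
- The cochlear stage is linear by default; compressive effects on the
  representation are available but untested against physiology.
- The separable transform's circular time convolution wraps slow-filter
  responses on very short notes; for the 250-ms stimuli and the 1-s probes
  used here the effect is negligible, but sub-100-ms inputs would need the
  linear-convolution path.
- Grid search optimizes a single (σ, C) for all pairwise classifiers; no
  per-pair tuning or probability calibration is attempted.
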