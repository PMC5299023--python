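# Methods

This note documents the models implemented in `strfkit`, the conventions
chosen where the design was genuinely open, and the scope of what the
simulation-based validation does and does not show.

## Periphery

Audio (16 kHz mono, no implicit resampling) is framed with 4 ms Hann
windows at a 2 ms hop ("4 ms windows with 2 ms overlap" is read as a 2 ms
hop, which produces the representation's 2 ms frame period), zero-padded to
a 128-point DFT, and converted to power.  Power is summed into trapezoid
Bark bands and compressed.

* **Bark scale.** The rational Traunmüller-style form
  z = 26.81 f / (1960 + f), with the usual additive constant (−0.53)
  dropped so that 0 Hz maps to 0 Bark and the scale is strictly increasing
  from the origin.  z(8 kHz) ≈ 21.53 Bark, so 21 channels of 1 Bark
  bandwidth (centers 0.5 … 20.5 Bark) tile the band of a 16 kHz signal.
  The channel count is derived from the configuration, not hard-coded:
  bands are emitted while their upper half-height edge stays below the
  Nyquist frequency's Bark value.
* **Trapezoid bands.** Unit-height plateau of half the bandwidth, linear
  flanks of half the bandwidth per side, so the half-height full width
  equals the nominal 1 Bark bandwidth and adjacent filters cross at half
  height.
* **Compression.** The cubic root is applied to *power* summed per band.
  Whether compression acts on magnitude or power, before or after band
  summation, is a convention; power-before-compression is chosen for its
  energy interpretation and fixed here.  Doubling the waveform amplitude
  therefore scales every output by 2^(2/3).

## Gabor atoms and the filter bank

An atom is the separable product of complex sinusoidal carriers
e^{i2πωx} and Hann envelopes along time (width b_t, ms) and frequency
(width b_s, Bark), sampled on the 21-channel × 50-frame patch grid with
centered axes.  The envelope is the *center-peaked* Hann
0.5 + 0.5 cos(2πx/b) on |x| < b/2: a support-edge-peaked variant would not
act as a window and contradicts the intended localized filter shapes, so
the center-peaked form is fixed here.

The bank covers the modulation plane up to half the Nyquist limits of the
patch grid — 125 Hz (half of the 250 Hz frame-rate Nyquist at 2 ms) and
0.25 cyc/Bark (half of 0.5 cyc/Bark at 1 Bark spacing).  Design rules:

* **Constant-Q widths.** b = 2 n_cycles / ω holds n_cycles carrier periods
  in the half-height envelope width (default n_cycles = 1), capped at the
  patch extent (100 ms / 21 Bark).  The DC value ω = 0 receives the capped
  width (envelope-only atom).
* **Lattice.** Modulation centers descend geometrically from the maximum
  while uncapped — adjacent Hann modulation transfer functions (half-height
  full width ≈ 1.44/b) then cross near half height — and linearly once the
  envelope is capped; 0 is always included.  At the defaults this yields
  temporal centers {0, 13.0, 27.7, 58.8, 125} Hz and spectral centers
  {0, 0.055, 0.118, 0.25} cyc/Bark.  Explicit per-axis lattices can be
  passed for simulation studies.
* **Orientations and parts.** Mixed atoms are emitted in both diagonal
  orientations (±ω_s).  For dictionary use the real and imaginary parts are
  separate real atoms; each is mean-subtracted (so that constant offsets
  cannot dominate matching-pursuit correlations) and normalized to unit
  Euclidean norm.  The imaginary part of the DC atom is identically zero
  and is not emitted.  The default bank holds 63 real atoms.

## STRF estimation

Stimulus windows are 50-frame (100 ms) sliding windows of the Bark
spectrogram preceding each response bin, flattened to D = 1050 and
column-centered (the zero-mean stimulus assumption of reverse correlation).
The proportionality in the STA and ridge formulas is resolved as the
N-sample average; downstream statistics are scale-invariant.

* **λ selection.** 5-fold cross-validation on *contiguous* blocks (lagged
  windows overlap, so contiguous folds leak less than interleaved ones);
  the grid defaults to 10^−4 … 10^4 times the mean Gram diagonal (9 log
  steps); ties break toward larger λ.  Folds with constant held-out
  responses are skipped with a warning.  Each fold's training Gram is
  eigendecomposed once so the λ sweep — and repeated estimation over many
  neurons sharing one stimulus — costs one rotation per solve.
* **Bootstrap mask.** 1000 subsamples of 20% of the response bins, drawn
  without replacement (a "20% of the data" subsample, independent of any
  duplication structure), one RNG stream per replicate spawned from the
  seed.  A coefficient is kept iff its bootstrap mean differs from zero in
  a two-sided z-test at α = 0.05.  The spread of m-out-of-N subsample
  estimates overstates the full-sample standard error by √(N/m − 1) (= 2 at
  20%), so the bootstrap standard deviation is rescaled by
  √((m/N)/(1 − m/N)) before testing; without this the test would be
  severely conservative.  With the correction the kept fraction under the
  null (responses independent of an iid stimulus) is ≈ α.  The correction
  is exact for estimators linear in the data items; at λ small relative to
  the subset Gram's sampling noise the test turns conservative again, so
  the calibration experiment in the validation suite fixes λ at the mean
  Gram diagonal (the center of the default grid).  No
  multiple-testing correction is applied — the per-coefficient p < 0.05
  rule is reproduced as a masking heuristic, not endorsed as simultaneous
  inference.  σ = 0 degenerates to keeping a coefficient iff its mean is
  non-zero.
* **Cleanup and inclusion.** Non-zero pixels whose entire (existing) 8
  neighbourhood is zero are removed in one simultaneous pass (idempotent by
  construction).  Fits are flagged "included" when the cross-validated
  prediction correlation reaches 0.25.

The null hypothesis for masking is coefficient = 0 (not a shuffled-response
null), and subsampling is per response bin; both are fixed conventions.

## Matching pursuit

The dictionary consists of every bank atom at every temporal placement
within the 50-frame patch (zero-filled, clipped atoms renormalized to unit
norm); spectral shifts are off by default (atoms span the full 21 bands)
but configurable.  Per iteration the element with the largest |inner
product| with the residual is selected; the signed inner product is the
entry's weight γ, and the projection γ·atom is subtracted.  Termination:
Pearson correlation between target and cumulative reconstruction ≥ θ, or
max_iter (default 50, reported via a warning, never silent).

* Negative weights are permitted; η uses |γ|.
* κ is evaluated on modulations in *normalized* units (cycles per frame,
  cycles per channel) in which both design maxima map to 0.25; this makes
  "diagonal" mean equal fractions of the two axis ranges.  By its
  definition as the L1 norm of an L2-normalized 2-vector, κ ∈ [1, √2]; the
  implementation does not rescale this range.  The DC atom (ω = 0) is a
  0/0 case and is assigned κ = 1 — an envelope-only atom is trivially
  separable.

## LNP simulator

Ripple stimuli are superpositions of n_components = 200 spectro-temporal
cosines with modulations drawn uniformly within the configured bounds
(defaults: the bank's 125 Hz × 0.25 cyc/Bark), random phases, and a
positive offset making the field nonnegative.  Amplitudes are tapered
toward low modulations by 1/(1 + |ω|/ω_half) per axis, with ω_half at 50%
of the temporal bound and 25% of the spectral bound — a low-pass,
spectrally-steeper bias emulating natural-sound (birdsong-like) modulation
spectra, whose spectral-modulation energy falls off faster toward its
Nyquist than the temporal side.  The exact birdsong-matched spectra of the
original recordings are not available; this generator is an explicit
synthetic stand-in.

Neurons apply a valid 2D correlation of the stimulus with the ground-truth
filter (drive aligned to the 100 ms window preceding each bin), a
rectified-linear nonlinearity thresholded at the drive median (exponential
optional; the rescaling to the target mean rate of 20 spikes/s makes the
relu gain a closed-form scale), and Poisson counts per 2 ms bin,
independent across the default 10 repetitions.  Everything is byte-exact
reproducible from (config, seed).

Defaults (120 s duration, 10 repeats, 20 spikes/s) are the simulated study
conditions; the multi-neuron recovery experiment shares one stimulus across
neurons — as a shared-ensemble physiology session would — which also lets
the estimator reuse its fold factorizations.

## Feature front-end

2D filtering uses 'same'-mode correlation along both axes (zero-padding in
time, edge clipping across channels), one output channel per spectral
alignment: 21 channels per filter, 1092 dimensions for 52 filters.
Complex Gabor outputs contribute their real part, consistent with treating
real/imaginary parts as separate filters elsewhere.  Channel subsampling
scans bottom-up from the first channel and keeps a channel iff it is at
least width/4 from the last kept one; widths come from the 1/e decay of
the Gabor spectral envelope (closed form b_s·arccos(2/e − 1)/π) or, for
STRFs, the smallest contiguous span around the energy centroid holding
90% of squared-coefficient energy (ties in the expansion go toward lower
channels).  PCA rotations are fit on training data only.  Temporal
resampling to coarser frame rates is mean-pooling by an integer factor
(default 5 → 10 ms).

The MFCC baseline pins one dialect: 25 ms periodic-Hann frames, 10 ms hop,
512-point power spectrum, 23 triangular mel filters over 0–8 kHz, log
compression, orthonormal DCT-II, 13 cepstra with c0 replaced by the log
frame energy, Δ by 7-point and ΔΔ by 9-point linear regression slopes with
edge replication — 39 dimensions per 10 ms step.

The synthetic event corpus provides six generator classes with distinct
modulation signatures (tone complexes, click trains, band-passed noise
bursts, AM tones, FM sweeps, modulated noise), peak-normalized, with
SNR-exact mixing of stationary or amplitude-modulated Gaussian noise.
Events are pooled to per-event vectors (frame mean + standard deviation)
before classification — per-event pooling is a fixed convention here.  The
classifier is a one-vs-all RBF SVM with winner-take-all decisions and
cross-validated grid search over the penalty and kernel width.

## What the validation shows — and what it does not

All quantitative checks run on synthetic data from the generators above.
They demonstrate internal correctness (matching-pursuit guarantees, κ/η
algebra, Poisson statistics, estimator calibration) and qualitative
phenomena: temporal-modulation filters re-estimate more faithfully than
spectral ones under ripple stimulation, estimates are "washed out" at high
modulations, correlated filter sets need fewer PCA components, and
spectro-temporal features match or beat spectral-only features in quiet.
They do not reproduce numbers tied to unavailable recordings or corpora
(specific receptive-field shapes, absolute classification accuracies), and
passing them does not certify behaviour on real neural data, where
nonlinearity, nonstationarity and correlated noise exceed what the LNP
model emulates.

Problem sizes used by the validation suite: 120 s stimuli for the
single-category recovery check, 30 s for the 20-neuron category
comparison, an iid-ensemble null calibration at D = 1050 with 1000
bootstrap replicates, and a 6-class × 20-events-per-class corpus for the
classification ordering.  The recovery medians are reported per category;
the half-Nyquist (125 Hz) filters recover least well, consistent with the
washout effect.

## Known limitations

* No adaptation, plasticity, or time-varying receptive fields; the linear
  stage is static by construction.
* Greedy matching pursuit only — no orthogonal MP or basis-pursuit
  variants; κ therefore inherits MP's greedy non-optimality, and the
  κ-vs-θ curve is not strictly monotone in general.
* The bootstrap mask reproduces a per-coefficient significance heuristic;
  it is not simultaneous inference.
* The Bark formula, trapezoid shape, Hann convention, lattice density and
  MFCC dialect are fixed, documented conventions; other choices would
  change numeric outputs without affecting the package's contracts.
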