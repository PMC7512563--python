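# Methods

This package classifies 2-D grayscale brain-MRI slices as benign or
malignant with a three-stage pipeline: multilevel Haar wavelet
decomposition, Tsallis-entropy summarization of each sub-band, and a
soft-margin RBF-kernel SVM whose hyperparameters — together with the
entropy's non-extensive parameter — are tuned by a DNA genetic algorithm
against a stratified five-fold cross-validation fitness. This note records
the model, its assumptions, the tunable parameters, the numerical choices,
and what the bundled phantom generator does and does not establish.

## Feature extraction

Images are clipped to non-negative intensities, rescaled to [0, 1] when
necessary, and resized bilinearly to 128×128. The dyadic side is required
so that a 3-level decimated 2-D Haar transform leaves a 16×16 = 256
coefficient approximation band; clinical slice formats (e.g. 181×217) do
not ceil-halve to a 16×16 deep approximation, so the resize is part of the
method's preprocessing contract rather than an optimization.

The transform uses the orthonormal Haar pair (1/√2, 1/√2) and
(1/√2, −1/√2), applied separably with symmetric (half-point) boundary
extension and decimation by two, keeping even-phase samples. Orthonormality
gives two testable invariants used throughout the suite: perfect
reconstruction (round-trip error ≤ 1e−8) and energy conservation (relative
error ≤ 1e−10) on dyadic sizes. Each level splits the current approximation
into LL, HL, LH, HH; the LL band feeds the next level. A J-level pyramid
yields 3J + 1 sub-bands, ordered LL_J, then (HL, LH, HH) for levels 1..J.

Each sub-band is reduced to one number: the Tsallis entropy
S_q = (1 − Σ p_i^q)/(q − 1) of its gray-level histogram. Coefficients are
min–max scaled onto 256 integer bins (mirroring 8-bit gray levels); a
constant band has no dynamic range and puts all mass in bin 0, making its
entropy exactly zero. Within 1e−9 of q = 1 the Shannon limit
−Σ p_i ln p_i is evaluated instead, since the algebraic limit of S_q is in
natural log; the display-oriented Shannon routine also supports base 2.
Min–max scaling makes the features invariant to affine intensity changes:
they are histogram-*shape* (texture) features, not brightness features.

The non-extensive parameter q weights the histogram: q < 1 emphasises rare
gray levels (e.g. a small hyperintense lesion), q > 1 the dominant tissue
peaks. Sub-extensivity arguments suggest q < 1 for brain tissue, but the
empirically best q can exceed 1, so the default search interval (0, 1) can
be widened to (0, 2) (`WIDE_Q_SPECS`); q is always searched, never fixed.

## Classifier

The SVM solves the usual soft-margin dual under the Gaussian kernel
K(x, y) = exp(−σ‖x − y‖²). Note the convention: σ multiplies the squared
distance (a gamma-style width), so larger σ means a more local kernel.
Features are standardized per column before the kernel, with statistics
estimated on the training data only (per training folds during CV);
squared Euclidean distances are scale-sensitive and the ten entropies span
different ranges. The dual is solved by libsvm (tolerance 1e−6, well below
the 1e−3 KKT margin-residual contract the tests enforce); the fitted model
exposes support vectors, dual coefficients α_i y_i and the bias, satisfies
0 ≤ α_i ≤ C and Σ α_i y_i = 0, and the test suite cross-checks its decision
function against an independent QP solve of the same dual. Malignant is the
positive class; a decision value of exactly zero breaks to malignant.

## DNA genetic algorithm

Chromosomes are strings over the quaternary base alphabet (C=0, T=1, A=2,
G=3), one gene of l = 8 digits per parameter (q, C, σ), so L = 24. Genes
are read big-endian as base-4 integers v and mapped affinely onto the
search interval, lower + v/(4^l − 1)·(upper − lower); the resolution
(upper − lower)/65535 is finer than any precision at which results are
reported. Defaults: population T = 20, G_max = 30, crossover probability
p_c = 0.8, per-digit mutation probability p_m = 0.02, stall tolerance
δ = 1e−4 over 3 consecutive generations.

Per generation: fitness evaluation; elitist binary tournament selection
(the best parent is copied into slot 0 and exempted from variation, making
the best-fitness trajectory non-decreasing); with probability p_c one
crossover operator chosen uniformly among transformation (swap two of the
five near-equal contiguous segments), permutation (replace a segment with
the homologous segment of a random other individual) and translocation
(excise a segment and reinsert it elsewhere); then per-digit mutation with
probability p_m, the operator uniform among the reversal (0↔2, 1↔3),
transition (0↔1, 2↔3) and exchange (0↔3, 1↔2) substitution maps and
uniform point mutation. The three maps are fixed-point-free involutions
with reversal∘transition = exchange — an algebra the tests pin down. The
loop stops at G_max or when the best fitness has moved less than δ for 3
consecutive generations; a single sub-δ step alone proved too eager a stop
under stochastic fitness landscapes. All randomness flows from one seeded
generator; no global state.

The fitness of a chromosome is the mean held-out accuracy over K = 5
stratified folds at its decoded (q, C, σ). Stratification keeps per-class
counts within one across folds; every class must have at least K members.
Hyperparameters are selected on the same folds whose mean accuracy is
reported (no nesting) — adequate for hyperparameter search, but the CV
fitness is accordingly an optimistically biased estimate of generalization.
After the search one final SVM is refit on all data at (q*, C*, σ*);
held-out confusion counts are still available via per-fold retraining at
the tuned parameters.

Wavelet pyramids and the per-sub-band histograms do not depend on q, so
they are computed once per image and cached; evaluating a chromosome only
re-weights cached histogram probabilities and trains K small SVMs. An
instrumentation counter on the transform makes this single-pass contract
observable in tests.

## Phantom generator

The generator emulates skull-stripped T2-weighted slices reduced to the
three main tissues: a dark background (0.0), a bright outer CSF band
(0.8), a gray-matter band (0.55) and a dark white-matter core (0.3),
drawn as concentric ellipses with per-draw jitter of ±4% on the semi-axes
and ±1.5% of the image side on the center, plus random orientation.
Malignancy is modeled as 1–3 hyperintense discs (intensity 0.95–1.0,
radii ~6–22 px at 128 px scale, i.e. roughly 1–4 cm at brain scale) placed
fully inside the parenchyma. Noise follows the MRI magnitude model
√((I + n₁)² + n₂²) with n₁, n₂ i.i.d. N(0, σ_n²) and
σ_n = rms(clean)/10^(SNR_dB/20); SNR ≥ 200 dB is treated as noiseless.
The jitter and contrast defaults were chosen so that the benign and
malignant populations are genuinely separable in at least one sub-band
entropy (> 3 pooled SD at 20 dB) while every phantom remains visibly
distinct — without a learnable generator, pipeline-level results would be
uninformative.

Two presets mirror common study designs: a balanced noise-sweep set
(45 + 45 images at each of 5/10/15/20 dB) and a 90-image clinical-style
set of 18 subtypes × 5 replicates (17 malignant subtypes differing in
lesion count, size and contrast, 1 benign), which stratifies to exactly
17 malignant + 1 benign per fold.

What passing tests on phantoms do *not* show: robustness to real
pathology diversity (infiltrative tumors, edema, mass effect), partial
volume effects, bias fields, or acquisition variability. The phantoms
establish that the pipeline recovers a planted, learnable contrast and
that its accuracy degrades monotonically with noise — a necessary sanity
property, not a clinical validation.

## Numerical choices and degenerate inputs

- Histogram binning: floor((v − min)/(max − min)·n_bins) clamped to the
  top bin; constant matrices short-circuit to bin 0.
- q ≤ 0 is rejected; |q − 1| < 1e−9 dispatches to the Shannon limit.
- Tie-breaks: tournament ties keep the first-drawn individual; a zero SVM
  decision value predicts malignant; constant feature columns get unit
  scale during standardization.
- All-zero images are classifiable (features identically zero) but have
  no defined SNR, so adding noise to them is an error.
- Problem sizes used in the shipped experiments: 90 images of 128×128,
  T = 20, G_max = 10 for the noise sweep (histogram caching makes one
  full GA run ≈ 1 s); the GA-quality checks use T = 30, G_max = 50 on
  analytic 1-D objectives against a 1e−4-resolution grid oracle.

## Known limitations

- Single-slice, binary classification only; no multi-class or volumetric
  handling.
- The deep-approximation size (256 coefficients) assumes the 128×128
  resize; other sizes change feature dimensionality only through 3J + 1.
- The CV fitness both guides the search and is the reported score; treat
  it as a model-selection criterion, not an unbiased accuracy estimate.
- Global histogram entropies discard all spatial information; lesions
  that alter texture without altering any sub-band histogram are
  invisible to the features.
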