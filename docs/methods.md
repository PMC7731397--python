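# Methods

This note records the scientific and numerical choices behind `seedxray`:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Synthetic radiographs

The generator renders stylised 2D X-ray projections of single seeds on a
fixed 224×224 grid, intensities in [0, 1], seed brighter than background
(high attenuation displayed bright; one polarity had to be fixed, and the
mask computation is polarity-aware regardless). A seed is an ellipse with
uniformly random orientation and semi-axes drawn from 15–30% of the frame
(the seed spans roughly 30–60% of the image, as in magnified single-seed
crops). The coat is the outer radial band (relative radius 0.82–1.0) at
intensity 0.92; the endosperm fills the interior at 0.65; the background
sits at 0.06. Degradation is a Gaussian point-spread blur (σ = 1 px)
followed by additive Gaussian noise (σ = 0.02), clipped to [0, 1] — the
simplest radiograph-like degradation; no physical X-ray transport or CT
geometry is attempted.

Class morphology:

* **viable** — uniform endosperm, regular outline (air-space fraction α = 0,
  irregularity 0);
* **nonviable/abnormal** — `n_blobs` dark elliptical cavities (intensity
  0.18 by default) clipped to the endosperm, with the *union* area
  iteratively calibrated to a target fraction α of the endosperm area
  (overlaps merged before accounting, converged to within 2%), plus a
  low-order sinusoidal perturbation of the outline with relative amplitude
  `irregularity` (default 0.08). Defaults: α = 0.15, 3 blobs.

α = 0 with irregularity 0 makes the two class-conditional distributions
coincide exactly — the null regime used for chance-level controls. All
randomness flows from one integer seed; each image draws from a child
stream keyed by (seed, image index), so manifests regenerate bit-identically.

The renderer also returns ground-truth masks (outline, endosperm, an
interior endosperm mask eroded clear of the blurred coat edge, cavities);
tests validate segmentation and area calibration against them. What the
generator does **not** emulate: realistic attenuation physics, embryo
structure, coat texture, scanner artifacts, or the continuum of mild
deterioration found in real seed lots. Passing tests therefore demonstrate
that the pipeline recovers morphological contrast of this kind, not any
particular accuracy on real radiographs.

## Preprocessing

Masking uses Otsu's between-class-variance criterion on a 256-bin
histogram; the foreground is the threshold side containing the central
pixel, holes are filled and the largest connected component kept. The mask
is computed once per seed, on `set_A`, and reused for all three
enhancement sets (an assumption: computing it per set changes nothing on
well-exposed images and would triple the cost).

The enhancement triplet: `set_A = image / max(image)`;
`set_B = clip((set_A − mean)/sd · s + 0.5, 0, 1)` with the display-range
slope `s = 0.15` (≈ ±3.3 standard deviations span the unit interval before
clipping; the mapping into display range is a configurable choice);
`set_C` is the 3×3 median of `set_B` with replicate (edge) padding so the
224×224 contract holds. Cropping resamples non-224×224 boxes bilinearly.
Constant or zero-max images raise degenerate-input errors rather than
producing NaNs.

## Texture features

Family counts are a hard contract — 6 + 234 + 67 + 5 + 28 + 8 = 348 per
image, 1044 per seed — validated at configuration time and again per
extraction. The exact parameterization inside each family is a documented
default, overridable through `FeatureBankConfig`:

* **Intensity (6):** mean, population sd, skewness, excess kurtosis, min,
  max over masked pixels. Moments of a constant region are defined as 0.
* **LBP (234):** 8-point codes at radii 1–4, neighbors sampled with
  bilinear interpolation and compared *strictly greater* than the center
  (with a 1e-9 slack so interpolation roundoff on flat patches cannot flip
  bits; a constant image maps to the all-zeros code). Per radius, the
  58-bin uniform-pattern (u2) histogram normalized over masked,
  border-valid pixels; non-uniform mass stays in the normalization but is
  not emitted. Two pooled statistics (energy Σp², entropy in bits of the
  radius-averaged code distribution) complete the 234.
* **Gabor (67):** 4 frequencies (0.08, 0.13, 0.20, 0.30 cycles/px) × 8
  orientations, one-octave-bandwidth complex kernels; per filter the
  masked mean magnitude and mean squared magnitude (64), plus the total
  energy J over the bank and the mean and sd of the per-filter means.
  Filtering runs in the Fourier domain with kernel spectra cached per
  image shape — a design choice for dataset-scale extraction speed
  (≈0.2 s per seed for all 1044 features, warm).
* **Contrast (5):** Michelson, RMS (sd), Weber against the background
  mean, range, interquartile range.
* **Haralick (28):** GLCM at distance 1 and offsets 0°/45°/90°/135°,
  32 gray levels quantized over the masked intensity range (stabilizes
  small-region statistics), symmetric and normalized, pairs touching
  background excluded; the 14 classic statistics (ASM, contrast,
  correlation, variance, IDM, sum average/variance/entropy, entropy,
  difference variance/entropy, both information measures of correlation,
  maximal correlation coefficient) summarized by mean and range over
  offsets. Undefined statistics on degenerate matrices are 0.
* **Fourier (8):** power spectrum of the masked, zero-filled image;
  4 equal radial bands over (0, 0.5] cycles/px excluding DC; per band the
  share of non-DC spectral energy and the energy-weighted circular mean
  phase.

Feature names encode family, parameters and enhancement set
(`i-LBP(2,17)[8,u2][B]`); the name parser also accepts the published
`[Max-X]`/`[sd-X]` block-tag style so reference selections can be
summarized with the same tooling. Those block tags are aggregation
notation from the original feature library and are deliberately not
reproduced in our own names: no allocation consistent with both the tags
and the printed family totals is derivable, so our defaults match the
totals, not necessarily the original internal allocation. Whether every
family was originally computed on all three enhancement sets is likewise
not documented; the default here is all three.

## Feature selection

Fisher score J = (μ₁−μ₂)²/(σ₁²+σ₂²) with population variances; J = 0 iff
the class means coincide, J is invariant to per-feature affine rescaling,
and a zero denominator with distinct means yields +inf (the feature is a
perfect separator in the filter sense). How the filter and the wrapper
interact was an open design point: here the Fisher ranking prunes the
candidate pool (default 150) and SFS then wraps cross-validated classifier
accuracy over that pool — consistent with "search strategy plus objective
function" and desk-scale runtime. SFS runs to `max_k` (default 60) and
reports the argmax of the accuracy curve; ties at a step break by higher
Fisher score, then lexicographic name, so traces are bit-reproducible
given the CV fold seed.

For honest end-to-end evaluation the package also provides
`FisherScoreSelector`, an sklearn-style transformer that refits the filter
inside each training fold; `reference_pipeline()` (selector →
standardizer → classifier) is the unit used in the statistical validation
suite. Selecting features on the full dataset *before* cross-validation
inflates accuracy far above chance on null data (we measured ≈87% at n=30
with 1044 candidate features); the nested pipeline scores ≈50–55% there,
as it must.

## Classification

LDA (shared covariance, svd solver — tolerant of singular pooled
covariance when p ≥ n), QDA (per-class covariances with a 1e-6 ridge) and
KNN (k = 5, Euclidean, majority vote) all sit behind per-fold z-score
standardization (mixed feature scales; documented assumption). Priors are
empirical class frequencies (balanced by construction). Evaluation is
10-fold stratified cross-validation; the report carries the fold
accuracies, their mean, and a 95% normal-approximation band
mean ± 1.96·sd/√10 — the confidence-interval definition was open, and the
normal approximation over folds matches the symmetric bands conventionally
reported; a binomial interval over pooled predictions would be the
defensible alternative.

## Augmentation and splitting

Six variants per image — rotation (±25°), horizontal reflection,
x/y translation (±10 px), x/y scaling (0.9–1.1) — mild, label-preserving
ranges (none were prescribed; all configurable). The original image is not
among the six, so n inputs give exactly 6n outputs (1282 → 7692). Empty
corners after warps fill with the border median. The 70:15:15
train/validation/test split is stratified by label and *grouped by source
image*: all variants of a seed share a partition. That grouping is
stricter than a plain random split and is deliberate — without it,
near-duplicates leak across partitions and inflate test accuracy.
Fractional per-class quotas roll forward between classes so the global
partition sizes land exactly on the ratio.

## ConvNet baseline

A deliberately small network: blocks of (3×3 stride-1 same-padding
convolution → ReLU → 2×2 max-pool) with 16/32/64 channels by default,
then one fully-connected layer and a softmax over the two classes;
cross-entropy loss, Adam (lr 1e-3), batch 16, 20 epochs. Implemented
directly on numpy (im2col convolutions, explicit backward passes) — at
these sizes CPU training takes seconds to minutes and stays deterministic
given the seed. Feature-map sizes follow the halving sequence from the
input resolution, which must be divisible by 2^depth. The depth and
widths of the original baseline were unspecified; these defaults are
chosen for desk-scale training and are fully configurable, including the
input resolution (the validation suite trains at 24–32 px on down-scaled
synthetic seeds). Pseudo-color conversion (grayscale replicated to three
channels) ships as a utility for color-input architectures and is unused
by this network. Transfer learning from large pretrained networks is out
of scope — it depends on externally trained weights.

## Problem sizes in the validation suite

Chosen as the package's own balance of statistical resolution and runtime:
effect-size monotonicity uses air-space fractions {0, 0.05, 0.15, 0.3} at
50 seeds/class with three repeated 10-fold CVs per arm; the SFS+LDA
end-to-end check runs at 50 seeds/class and α = 0.3 (threshold ≥ 90% CV
accuracy); chance-level controls use the α = 0 arm and label permutation
(50% ± 10%); the ConvNet generalization check trains 120 images at 32 px
(threshold ≥ 85%) and its permutation control 300 images at 24 px. The
permutation controls need samples in the hundreds: with n in the low
hundreds the random overlap between permuted and true labels lets a
flexible model track the true class several points above 50% without any
leak — an expected finite-sample effect, not a bug.

## Known limitations

* Synthetic morphology is far cleaner than real radiographs; the default
  classes are nearly perfectly separable, which validates mechanics and
  monotonic behavior, not field performance.
* The exact internal allocation of the published 234/67/8 LBP/Gabor/
  Fourier feature sets is not recoverable from their printed totals; only
  the totals are contractual here.
* Germination-rate arithmetic rounds half-up to integer percent;
  selection-composition shares round half-even to one decimal (the
  convention that reproduces the published shares exactly).
* The KNN tie-break (nearest neighbor's class) can only matter for even k
  or >2 classes; with k = 5 and two classes it never fires.
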