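# Methods

This note records the models, conventions and numerical choices behind
`skinhsi`, in the order data flows through the pipeline.

## Reflectance model and data conventions

Raw captures hold sensor counts `I(x, y, λ)` with a dark-current frame `Ib`
and a white-reference frame `Iw`; both references may be per-band vectors
(spatially uniform) or full per-pixel frames, since acquisition rigs differ
in whether they record a flat-field. Normalized reflectance is
`r = (I − Ib) / (Iw − Ib)` per pixel per band. Values outside [0, 1]
(specular glints, noise) are **preserved by default** — silent clipping
would bias every variance-based reducer downstream; clipping is an explicit
flag. The normalization raises an error listing band indices wherever
`Iw ≤ Ib`.

Coordinates are 0-based and row-major; rectangles are half-open
`(row0, row1, col0, col1)`; the tumor class is positive everywhere. The
default band grid is 311 uniform points over 420–750 nm (≈1.065 nm
spacing). The acquisition literature this emulates reports the 311-point
count and the 420–750 nm range without stating the spacing; a uniform grid
is this package's convention, chosen so the hemoglobin twin bands are
resolved by dozens of bands.

RGB previews integrate reflectance against embedded abridged (10 nm) CIE
1931 2° color-matching functions under D65, normalized by the luminance sum
on the cube's own grid, then `xyz2rgb` with clipping. The abridged tables
are accurate to well under 1% of the white point, ample for previews and
for the color-space tissue masking below.

## Tissue masking

The specimen rests on a consistently near-black surface, so background
removal is a color problem: render to RGB, convert to L\*a\*b\*, K-means
with 6 clusters on (a\*, b\*), keep the best of 3 restarts by
within-cluster sum of squares (seeded k-means++ for determinism). Any
cluster owning a pixel on the outer one-pixel border is background;
remaining pixels are tissue; binary closing with a disk of radius 3 px
fills pinholes. "Run clustering three times" is interpreted as three
random restarts keeping the lowest-inertia solution — the natural reading
for a stochastic clusterer; iterative re-segmentation was considered and
rejected because no merge criterion between rounds is defined. If every
cluster touches the border the masker raises "no foreground found" rather
than guessing.

## Unmixing

SAM is computed on reflectance as-is (no continuum removal):
`arccos` of the normalized inner product, clamped to [0, π]; nonnegative
spectra land in [0, π/2]. N-FINDR projects spectra to `n − 1` dimensions by
PCA, seeds the simplex with `n` random **distinct** pixels, and performs
full replacement sweeps — each vertex in turn is swapped for the pixel that
most increases the simplex `|det|` volume — until a sweep changes nothing
(a 50-sweep guard bounds pathological cycling; in practice convergence
takes a handful of sweeps). Termination at a sweep fixed point guarantees
single-swap local optimality, which the tests verify exhaustively, and on
clean simplex data the sweeps recover the true vertices (verified against a
brute-force max-volume search over all pixel triplets).

Cluster assignment is the per-pixel SAM argmin over endmembers, ties toward
the lower endmember index. Zero-norm pixels (SAM undefined) fall back to
cluster 0 and are counted, not fatal: masked cubes can legitimately contain
dead pixels.

## Dimension reduction

All reducers expose `k` output columns and are seeded. PCA is a
mean-centered eigendecomposition of the band covariance with a fixed sign
convention (each component's largest-|loading| element is positive), so
scores are exactly reproducible and single-cluster ClusterPCA/SuperPCA
equal plain PCA bit-for-bit.

**ClusterPCA** caps per-cluster dimensionality at `cluster_size − 1` and
zero-pads scores back to `k`, because PCA on an m-pixel cluster has at most
m − 1 meaningful components. Clusters with fewer than two pixels are merged
into the cluster of the spectrally nearest endmember; empty clusters are
dropped (per-cluster PCA is undefined on them), so `n` is an upper bound.

**SuperPCA** oversegments the tissue with SLIC (compactness 10) on the
first three global PCA score channels, min-max scaled; the per-superpixel
PCA machinery is shared with ClusterPCA. SLIC was chosen because it is the
standard mask-aware oversegmenter in the scientific Python stack; the
achieved superpixel count is a segmentation outcome, contract-bounded to
[10, 30] when 20 are requested. SuperPCA's transform is only defined for
the fitted sample's geometry — superpixels are spatial, sample-specific
objects — whereas ClusterPCA generalizes to arbitrary spectra via SAM
assignment to its stored endmembers.

**Multiscale variants** fit one model per scale (duplicates dropped with a
warning) and return per-scale feature blocks; fusing is a classifier-level
concern (below). Default scale sets: {2, 5, 6, 8, 10} endmembers for
MClusterPCA, {9, 14, 20, 28, 40} superpixels for MSuperPCA.

**MSelect** picks the grid band nearest each marker wavelength (540 nm
hemoglobin, 650 nm melanin), since the markers need not sit on the grid;
k is fixed at 2. **LDA** yields one axis for the binary problem; a singular
within-class scatter raises an error advising PCA-LDA, which denoises with
m PCA components first (m defaults to the sweep's k, 10 in the classic
configuration). **RFI** trains AdaBoost (SAMME) over depth-3 Gini trees —
the binary-case equivalent of AdaBoostM2-boosted weak learners — and keeps
the k highest-importance bands, ties toward the lower wavelength. Boosted
ensembles concentrate importance on few bands even under null labels, so
the meaningful null check is discriminative (planted-signal importance mass
must dominate the null's in the signal window), not a max-vs-median ratio.
**FastICA** delegates to scikit-learn; non-convergence is flagged on the
model and warned, with the partial result returned. **RICA** is a tied-
weight reconstruction ICA minimizing
`‖XWᵀW − X‖²/n + λ·Σ smooth-L1(XWᵀ)/n` (λ = 0.5, smooth-L1 via
`sqrt(h² + 1e-8)`) with analytic-gradient L-BFGS on standardized spectra —
unconstrained, so it supports overcomplete bases. The **autoencoder** is a
single hidden layer of k units trained input-to-input (lbfgs, logistic by
default, identity/tanh/relu selectable) on standardized spectra;
`reconstruction_mse_` is reported in that standardized space.

Training scope follows the experimental protocol: every reducer is fitted
per sample except LDA, PCA-LDA, RFI and AE, which are fitted dataset-wide —
inside cross-validation, on the training folds only.

## Segmentation protocol

Features are z-scored with training statistics inside the classifier
pipeline (reducer outputs arrive on wildly different scales and the RBF
kernel is not scale-invariant). The SVM uses the ν-parameterization
(`NuSVC`, ν = outlier fraction, default 0.05): ν upper-bounds the fraction
of margin violations, which is the natural reading of a "5% outlier rate";
libsvm rescales the ν-SVC solution so violations are countable as
`y·f(x) < 1`. Kernel scale defaults to `gamma="scale"`. An optional
`false_negative_penalty` up-weights the tumor class (default off).

Cross-validation shuffles the sample list by seed and deals samples
round-robin into 5 folds (16 samples → sizes {4, 3, 3, 3, 3}). Within each
fold, training pixels are subsampled to at most 400 per sample (seeded) to
keep kernel matrices tractable; validation predicts *every* tissue pixel of
the held-out samples. Per-fold metrics pool the fold's validation pixels;
summaries are mean ± SEM (sample SD / √n) across folds, matching the
fold-averaged presentation convention. Multiscale methods train one SVM per
scale and fuse per-pixel predictions by strict majority, ties → non-tumor
(the conservative call for margin drawing). Dimension sweeps pick the best
k by mean Jaccard, ties toward the smaller (cheaper) model; k values beyond
the band count are skipped with a warning.

Jaccard over an empty union (neither mask has a positive pixel) is defined
as 1 with a warning; undefined confusion metrics are reported as missing
rather than silently zero.

## Synthetic scene generator

The generator is the package's stand-in for clinical data and defines the
conditions everything is tested under:

* **Geometry** — an elliptical tissue region (semi-axes ≈42%/44% of the
  frame, jittered) on a flat dark background (reflectance 0.04); an
  elliptical tumor placed wholly inside the tissue and sized so tumor
  pixels are 32% of tissue pixels (±5%, matching the prevalence of the
  clinical protocol this emulates). Default frames are 72×72 px (tests use
  40–56 px); clinical ROIs run to 500×700, and all algorithms are
  resolution-independent, so desk-scale frames change runtimes, not
  conclusions.
* **Spectra** — Beer–Lambert attenuation
  `r(λ) = r_base(λ)·exp(−Σ cᵢ εᵢ(λ))` with `r_base` a smooth bright ramp
  (0.55→0.65) and embedded relative extinction curves: HbO2 (Soret band,
  α/β bands anchored at 576/542 nm with the 560 nm valley), Hb (Soret at
  430 nm, broad 556 nm band, steep 600 nm knee, weak 760 nm band), and
  eumelanin (tabulated λ^−3.33 power law, strictly decreasing). Curves are
  linearly interpolated onto the grid and rescaled to max 1, so
  concentrations are unitless loadings. Baseline loadings (melanin 0.8,
  HbO2 0.5, Hb 0.35) give skin-like reflectance (~0.2 in the green, ~0.5
  in the red).
* **Biology** — smooth random concentration fields (Gaussian-filtered
  noise, σ = 6 px, 12% pointwise SD) emulate macroscopic chromophore
  heterogeneity; tumor pixels multiply melanin by 1.8 and both hemoglobins
  by 2.2 (melanocytic proliferation and angiogenesis). Dataset generation
  jitters baseline loadings ±15% and contrast ±10% per scene to emulate
  patient variability, with per-scene seeds derived from a master seed.
* **Artifacts** — blood stains: small disks outside the tumor with 2.5×
  hemoglobin; dye marks: spectrally flat dark disks (transmittance 0.2).
* **Sensor** — per-band dark (~100 counts) and white (dark + 3500×D65
  shape) frames; raw counts `dark + r·(white − dark)` plus additive
  Gaussian noise expressed in reflectance units (default SD 0.003) and
  scaled by the dynamic range.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical data: multilayer radiative transport (a single
Beer–Lambert layer cannot reproduce depth-dependent scattering), hair
follicles and inflammation, camera PSF and wavelength-correlated sensor
noise, bilirubin and water absorption, and pathologist label noise at the
margin. Synthetic contrast is also cleaner than clinical contrast: the
raw-spectrum baseline reaches >90% validation Jaccard here versus ~47% on
real specimens, so absolute metric levels are not transferable; *relative*
behaviors (scope effects, eigenvector–chromophore correspondence, fusion
behavior) are what the synthetic studies establish.

## Eigenvector–chromophore correspondence

On the seeded default scene, per-sample PCA reproduces the expected optical
structure: the first eigenvector tracks the flat base-reflectance component
(|projection onto the uniform vector| > 0.8), and an early eigenvector
(including the third) carries the HbO2 twin-peak signature. The detector
(`dimred.has_twin_peak_signature`) demands a *clean* peak(≈542)–valley–
peak(≈576) pattern after 5-band smoothing: extrema within ±6 nm of both
bands, same deflection direction, an opposite extremum between, and at most
five interior extrema in the 515–605 nm window. The extrema-count cap is
what separates hemoglobin loadings from smoothed-noise loadings;
prominence-based criteria alone could not (verified on hemoglobin-free
control scenes, where the detector correctly stays silent).

## Degenerate inputs and tie-breaks (summary)

All-identical spectra → N-FINDR error; empty tissue mask → flatten error;
all clusters touch the border → masking error; SAM ties → lower endmember
index; vote ties → non-tumor; best-k ties → smaller k; RFI importance ties
→ lower wavelength; zero-norm pixels → cluster-0 fallback with a counter;
duplicate scales/k values → deduplicated with warnings.

## Problem sizes

Tests and the acceptance script run 40–72 px scenes, 10-scene datasets,
≤400 training pixels per sample, and oracle problems small enough for
exhaustive search (≤60 pixels for triplet enumeration, 20×5 for dense
eigendecomposition) — sizes chosen so every oracle is computable exactly
while every code path, including the full CV loop, is exercised.
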