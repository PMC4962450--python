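# Methods

This note documents the models, numerical choices and limitations of
`optiscreen`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Multimodal preprocessing

A multimodal image is a mosaic of square tile scans with three
co-registered channels (CARS → red, TPEF → green, SHG → blue),
non-negative float intensities. The preprocessing order is fixed:

1. **Median filter** (square window, side `2r+1`, default `r = 1`,
   reflective edges) — removes shot-noise speckle.
2. **Block-mean downsampling** (default factor 4; a 1024×1024 tile
   becomes 256×256). Dimensions not divisible by the factor are cropped
   to the largest divisible extent and logged.
3. **Per-tile illumination correction** (below).
4. **Per-channel contrast stretch**: intensities below the `low_tail`
   quantile and above the `1 − high_tail` quantile are clipped, then
   linearly rescaled to [0, 1]. Defaults (CARS (0.05, 0.015),
   TPEF (0.05, 0.04), SHG (0.001, 0.001)) are read as (low, high)
   saturation fractions; both tails are configurable per channel. A
   degenerate channel (coinciding quantiles) maps to zero with a
   warning.

### Illumination correction

Tile scans carry a common optical vignette plus tile-to-tile gain
steps. Two calibration-free estimators are provided
(`correct_tile_illumination(method=...)`):

* **`shared-profile`** (default). The vignette is identical in every
  tile, so the per-channel profile is estimated as the Gaussian-blurred
  (σ = tile side / 4) average of mean-normalized tiles — tile *content*
  averages out of the estimate as the tile count grows. Each tile is
  divided by the unit-mean profile and by a robust per-tile gain, its
  upper-decile brightness relative to the channel's, clamped to
  [0.5, 2] so nearly-empty tiles are not amplified to tissue
  brightness.
* **`tile-blur`**. The classical retrospective flat-field: the field is
  the heavy Gaussian blur (σ = tile side / 4) of the tile itself,
  floored at `eps` (default 0.3) times the channel-wide field median,
  divided out, and rescaled by the channel's mean illumination level.
  Works without repeated tiles but leaks genuine image structure at
  scales above σ into the field; on synthetic scenes this measurably
  distorts the linear relation between channels and reference colors,
  which is why `shared-profile` is the default.

Both estimators leave a flat image unchanged and remove a pure gain
step between tiles of identical content (unit-tested). Both rescale to
a *channel-global* reference rather than preserving each tile's own
mean: per-tile mean preservation would re-introduce exactly the
tile-to-tile gain steps the correction exists to remove.

## 2. Pseudo-H&E staining

* **Color model.** PLS2 regression (NIPALS, via scikit-learn) of H&E
  RGB on the three preprocessed channels, 3 components by default,
  trained on one registered image pair; training is restricted to
  tissue foreground (background and nuclei excluded) since those pixels
  are overwritten at compositing time. The fitted model is distilled to
  a plain affine map `y = x·Aᵀ + b` (clipped to [0, 1]); with full-rank
  inputs and 3 components it coincides with ordinary least squares
  (unit-tested against the normal equations at 1e-8 RMSE).
* **Nuclei model.** Two-class Gaussian LDA with pooled covariance on
  the raw 3-channel intensities (no texture features); posterior
  threshold 0.5; connected components below `min_area` (default 4 px at
  post-downsampling scale) are removed. A near-singular pooled
  covariance (condition > 1e10) is ridge-regularized by
  `1e-6 · trace/3` on the diagonal with a warning. Prediction accepts
  an optional exclusion mask: synthetic background and nuclei are both
  dark in every channel, and a single linear boundary cannot carve out
  a middle intensity band, so the pipeline restricts nuclei detection
  to tissue foreground (the background weight handles the rest).
* **Background weight.** k-means (k = 6, k-means++ init, 10 restarts,
  fixed seed) on per-pixel channel triples; the cluster whose center
  has the smallest squared norm is background. The binary mask is
  median filtered (disk r = 2), the foreground morphologically closed
  (disk r = 5, fills gaps), the background opened (disk r = 5, removes
  islands), and a disk mean filter (r = 7) turns the mask into smooth
  weights in [0, 1]. Radii are in post-downsampling pixels, sized for
  256×256 maps; scale them with the map. `mean_radius = 0` keeps the
  weight binary.
* **Compositing.** `out = w·white + (1 − w)·(nucleus ? violet : color)`
  per pixel and channel — a convex combination, so outputs stay within
  the hull of {white, nuclei color, predicted color}. The nuclei color
  defaults to dark violet (0.29, 0.13, 0.37); the hue is conventional,
  the RGB a package choice, both configurable.

## 3. Raman pre-treatment

Per spectrum: crop to the fingerprint range (default 600–1800 cm⁻¹) →
SNIP background subtraction → vector (unit Euclidean norm)
normalization. Spectra with zero norm after subtraction are flagged
invalid and excluded downstream with a log entry.

**SNIP.** Optional LLS compression `v = log(log(√(y+1)+1)+1)`; then for
window p from m down to 1 (decreasing-window variant, which reduces
peak erosion), `v[i] ← min(v[i], (v[i−p] + v[i+p])/2)` for interior i;
inverse transform. Points never lowered by clipping are returned
bit-exact, so a constant spectrum yields an exactly zero corrected
signal. The maximum window m must exceed the half-width of the widest
peak (bands here: σ ≈ 9 cm⁻¹ ≈ 4.5 channels at 2 cm⁻¹ steps), but each
clipping pass also bites into genuinely *concave* baseline curvature,
and the bias accumulates with m: on the synthetic fluorescence
baselines m = 60 removes ≈0.27 intensity units of real baseline into
the signal (class-mean/truth correlation 0.84), while m = 30 is
essentially unbiased there (r ≥ 0.99). The default is therefore
**m = 30**, LLS on; both configurable.

**PCA.** Mean-centred, via SVD (covariance eigendecomposition when
features ≤ samples, for speed); loadings orthonormal with the sign
convention that each loading's largest-magnitude element is positive;
explained-variance fractions non-increasing. The classification
dimension defaults to the smallest count reaching 99% explained
variance, capped at 20.

Optional cosmic-ray clamping is deliberately absent by default: spike
regions are handled as excluded annotation classes.

## 4. Spectral histopathology

* **Annotation transfer.** Per-scan k-means (default k = 9, range 9–15,
  k-means++ with 10 restarts, fixed seed) on PCA scores; each cluster
  is mapped to a diagnostic class or an excluded category (muscle,
  connective, background, spikes, hyperplasia). In synthetic runs the
  "pathologist" maps each cluster to the majority ground-truth class of
  its member pixels, mirroring blinded annotation on a parallel H&E
  section. Clustering is per scan (not pooled per individual).
* **Regions.** One annotated class area within one scan
  (`individual|scan|class`). Confusion statistics default to region
  level — each region's predicted class is the majority vote of its
  spectrum predictions, ties resolved toward the earlier class in
  (adenoma, carcinoma, normal) — with spectrum-level reporting
  available.
* **KKNN.** k nearest training rows by Minkowski-p distance (defaults
  k = 1, p = 2). Distances are rank-normalized by the (k+1)-th
  neighbour distance; kernel weights are applied and summed per class.
  The 'optimal' kernel uses the published rank-based optimal weighting
  scheme for k-NN (weights depend on the rank, k and the feature
  dimension); 'rectangular', 'triangular' and 'inv' weight by the
  normalized distances. With k = 1 — the operating point of the
  workflow — every kernel reduces to plain nearest-neighbour. Exact
  distance ties resolve toward the earlier training row; remaining vote
  ties toward the smaller class index. Neighbour search uses an
  optimized library query (Euclidean) or chunked partial selection, with
  a candidate re-sort enforcing the documented tie-break.
* **IO-CV.** One fold per individual; the fold's spectra are predicted
  by a model trained on all other individuals; predictions are pooled
  before scoring. Folds whose training set lacks a class are recorded
  and proceed with the remaining classes.
* **Statistics.** sensitivity_c = diag_c / rowsum_c · 100;
  specificity_c = TN_c / (TN_c + FP_c) · 100 one-vs-rest; mean
  sensitivity is the unweighted macro average (a zero annotated row
  reports NaN and is excluded from the mean). Merging sums the rows and
  columns of grouped classes (tumor = adenoma + carcinoma) and
  preserves the total count.
* **Wilcoxon screen.** Two-sided two-sample rank-sum per listed
  principal component (1-based numbering), exact null distribution for
  small tie-free samples, normal approximation with tie correction
  otherwise (scipy).

## 5. Synthetic data: the stated world

**Image scenes.** Background is a smooth random-field region occupying
the requested area fraction (default 0.30), nearly dark (×0.04) in all
channels. Tissue: TPEF diffuse cytoplasm (0.60 ± 0.12 smooth), CARS dim
matrix (≈0.18) with bright lipid blobs (0.75–0.95, radii 4–10 px), SHG
sparse smoothed random-walk fibers (0.85 on a 0.06 floor). Nuclei are
disks (radii 14–22 px at full scale) that darken all channels
multiplicatively by a factor 0.2–0.5 (negative contrast). The reference
H&E is an exact affine map of the clean channels plus dark-violet
nuclei and white background — so color fidelity of the full pipeline is
measurable. Illumination is per tile: a radial vignette and a random
gain, both scaled by `vignetting_strength` (default 0.3; 0 gives an
identically-1 field); additive Gaussian noise (σ = 0.02 on a [0, 1]
scale) is an engineering choice, as no noise statistics are published
for the modality. The generator does **not** emulate optical
point-spread functions, photophysics, stain chemistry, registration
error or spatial texture inside nuclei; a green fidelity test
establishes that the algorithmic chain preserves an affine color
relation under tiling artifacts and mild noise, not photorealism.

**Raman cohorts.** Default geometry mirrors a small murine colon study:
6 individuals × 6 scans, 34×40 pixels per scan (1360 spectra), axis
600–1800 cm⁻¹ step 2. Each spectrum is a sum of Gaussian bands
(σ = 9 cm⁻¹) at 785 (DNA phosphate backbone, rising along the
adenoma–carcinoma sequence), 1003 (phenylalanine), 1449 (CH₂
deformation) and 1657 cm⁻¹ (amide I), with per-class amplitudes
(0.2–1.1 a.u.) chosen so that every class pair differs by ≥ 0.25 at
some band — five times the default noise σ of 0.05; per-individual
band-amplitude effects are multiplicative 1 + N(0, 0.05), shared across
an individual's scans. Baselines are a broad fluorescence hump
(σ = 320 cm⁻¹) plus a random cubic, scaled ±20% per pixel. Class
layouts are contiguous regions (one primary tissue class per scan,
cycling normal → adenoma → carcinoma, a background wedge, muscle
stripes on alternating scans), matching region-level annotation
granularity. Band shapes are Gaussian (not Voigt/Lorentzian), there are
no cosmic-ray spikes, no wavenumber miscalibration, and no
within-region class mixtures; perfect (100%) IO-CV sensitivity on the
defaults is the expected behaviour of a well-separated stated world,
not a claim about real tissue.

## 6. Reproducibility and numerics

One master seed drives every run; per-stage seeds derive from it by a
fixed affine counter (`(1009·seed + 101·stage + 7) mod 2³¹`), and all
k-means calls take explicit seeds, so reports are bit-reproducible.
Run configurations are schema-validated (unknown keys rejected) and
embedded, with a hash, in every report. Images are floating point in
[0, 1] throughout; 8-bit conversion happens only at export. Degenerate
inputs (constant channels, zero-norm spectra, singular covariances,
empty masks) degrade with warnings or flags rather than exceptions
wherever the pipeline can proceed.

## 7. Known limitations

* The pseudo-H&E fidelity criterion is evaluated on strict non-nuclei
  foreground (eroded by the mean-filter radius): the background weight
  deliberately feathers tissue edges toward white, so a band near the
  specimen contour is excluded from the color comparison by design.
* Blind illumination correction cannot fully distinguish tile-scale
  content from gain; the shared-profile estimator assumes several
  tiles with statistically similar content.
* Region-level scoring assumes each annotated region carries one
  diagnosis; mixed regions would need finer annotation.
* The LDA nuclei detector operates on single-pixel intensities with an
  area post-filter; it approximates, but is not identical to,
  region-based fingerprinting.
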