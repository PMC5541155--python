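# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. It is the companion to the README's overview.

## Representation

An instance is `{𝒜, s}`: `s` the ordered landmark configuration (0-based
`(row, col)` coordinates, pixel centers at integers, subpixel allowed) and
`𝒜` the appearance pyramid — for each landmark n and retained level
l ∈ K_n, a p×p patch of pyramid level l sampled by bilinear interpolation
around `x_n / 2^(l-1)` with edge replication outside the level. Patches
are concatenated landmark-major, level-minor, and flattened row-major into
one vector; the vectorization is a bijection given (N, K, p).

**Pyramids.** The Gaussian pyramid smooths (σ = 1.0, reflect boundary) and
keeps even-index samples per octave; its channels are redundant. The
wavelet pyramid multiplies the image spectrum by L radially symmetric
windows and inverts each product, downsampling level l by cropping the
fftshift-centered central `1/2^(l-1)` region per axis (half-open ranges,
odd sizes round up). The windows are raised-cosine steps in log₂
frequency with octave cutoffs at `π/2^l` and a transition of 0.5 octave
(default): squared windows telescope to exactly 1 per frequency bin, the
last window keeps all lower frequencies (low-pass residual). Because each
window's support lies inside the cropped region, analysis→synthesis
(pad spectra back, re-apply windows, sum, invert) reconstructs the image
to floating-point accuracy, and band energies partition the image energy
(Parseval). Note the synthesis re-applies the analysis window, so zeroing
one level removes the `W_l²`-weighted spectrum — the error energy is
`Σ W_l⁴|F|²`, equal to the band energy only where bands do not overlap.

**Trimming.** Coarse patches redundant with their neighbours' are removed
greedily: the score of patch (n, l ≥ 2) is the mean over training samples
of the normalized L2 distance (patches mean-centered and scaled to unit
norm) to the nearest same-level patch among the k = 2 nearest landmarks
by mean-shape distance; the least-scoring patch is deleted while the
least score is below the threshold (strictly), so threshold 0 trims
nothing. When all of a patch's neighbours have already lost the level,
the score falls back to their untrimmed training patches — redundancy is
transitive, and without the fallback nothing could fully trim. Level-1
patches are never removed. Ties break by lowest landmark index, then
lowest level; the result is independent of training-sample order.

## Priors

Appearance vectors are z-scored per sample (mean 0, variance 1; constant
vectors map to zero) before PCA. Shapes are translation-aligned to the
mean centroid — no rotation/scale Procrustes, because the MAP fusion mixes
the prior with pixel-coordinate predictions in one frame, which is only
consistent if the prior lives in (translated) image coordinates. A useful
consequence: after centroid alignment no principal direction carries net
translation, so the shape prior penalizes deformation but not position.

PCA is computed by economy SVD of the centered data (the Gram route when
dimension ≫ samples); eigenvalues use divisor M−1; the retained count is
the smallest whose cumulative eigenvalue share reaches the variance
fraction (default 0.95 for both shape and appearance). Shape plausibility
is the Mahalanobis log-density `−½ Σ b_j²/λ_j` in mode coordinates.

## Explicit fitter (subspace LK + MAP shape)

Patch search minimizes the residual against the mean-appearance template
in the orthogonal complement of the appearance eigenspace. Per patch we
precompute: the template block `T` of the (normalized) mean appearance;
an orthonormal basis `Q` of the appearance eigenvector rows belonging to
that block (SVD, cutoff 1e-8) — the block's learned variation directions;
and the steepest-descent images `G⊥ = (I − QQᵀ) ∂T/∂x` (central
differences) with pseudo-inverse (cutoff 1e-8). Each iteration projects
the residual by `(I − QQᵀ)` and updates the position by `−G⊥⁺ r`,
converted to the level-1 frame by `2^(l-1)`. Two safeguards keep the
linearization honest: a per-iteration trust region of p/4 level-l pixels
and a total wander cap of p/2 (half the patch) — a search that hits the
cap no longer observes its original patch and is reported with maximal
uncertainty. A textureless observation (variance ≈ 0) yields no update
and maximal uncertainty.

Within a full fit, the global projector is honored: once per outer
iteration the full appearance vector at the current shape is extracted,
normalized with frozen statistics, and its eigenspace component
`P_𝒜(P_𝒜ᵀ(𝒜 − 𝒜̄))` is computed once; each patch's residual subtracts its
frozen slice of that correction. A standalone `lk_search` without this
context uses the per-block projector alone with per-patch z-scoring.

The prediction confidence is σ² = mean squared projected residual
(computed after projection; the unprojected alternative would also charge
the search for appearance variation it cannot reduce), floored at 1e-6
and capped at the larger of the observation's and template's variance —
in the normalized intensity units of the residual, so the cap bounds the
weight range without silencing bad matches.

The MAP shape solves the 2N×2N linear system assembled from
`P_sΛ⁻¹P_sᵀ` and the per-prediction inverse variances (each σ²_{n,l}
duplicated for row and column); trimmed (n, l) pairs contribute zero
weight. The system is nonsingular because level 1 is always retained and
σ² is floored. `fit_explicit` alternates all searches with the MAP shape
and stops when mean landmark motion < 0.05 px or after `outer_iters`.

*Accuracy floor.* The PCA truncation residual maps through `G⊥⁺` into a
position bias of roughly 0.5–0.8 px on the phantom; instances whose
initialization error is already below this floor may not improve. The
explicit fitter is paired with the Gaussian pyramid: on the wavelet
pyramid the finest level is a high-pass subband, which is nearly empty
on smooth content and gives LK no gradient signal.

## Implicit fitter (SDM cascade)

Features are per-patch HOG descriptors over the full trimmed appearance
pyramid (not level-1 only): unsigned orientations in [0, π) hard-assigned
to 9 bins (bin 0 = horizontal gradients), magnitude-weighted over 4×4
cells, single block, L2-hys normalization (clip 0.2). Patches are cropped
to the largest cell-divisible side (17 → 16). Intensity features (the
z-scored vectorized AP) are available as an alternative.

Each stage solves multi-output ridge regression in closed form with the
bias excluded from the penalty (features and targets centered; primal or
dual normal equations, whichever Gram is smaller; minimum-norm lstsq when
λ = 0). The default λ = 0.01·trace(Gram)/dim is scale-aware and involves
no cross-validation. Stage i+1's training shapes are produced by applying
stage i. The initial shape is the mean training shape (the "average shape
at the average location"); optional seeded augmentation adds random
translations (σ 3 px) and log-normal scalings (σ 0.05) of it, off by
default. Training is bitwise deterministic given (data, seed, config).

## Classification

Φ = [b_s, b_A] at the fitted shape (b_s from the centroid-aligned
projection, b_A from the normalized appearance). A further PCA (fraction
0.95) gives b_Φ; AdaBoost (SAMME) with 100 depth-2 trees predicts the
label; grading is treated as plain 3-class classification with MAE/RMSE
computed post hoc on integer-coded grades {0, 1, 2} — ordinal regression
was the design alternative and was not pursued.

## Synthetic phantom

The generator emulates a disc-level axial view: an outer disc-like
ellipse (25 landmarks) and an inner canal-like ellipse (12 landmarks,
default N = 37) on a 128×128 grid, deformed by orthonormal modes —
(1) radial canal narrowing, (2) anisotropic disc scaling, (3) bending,
further modes low-frequency radial ripples. Modes are projected off rigid
translations (position is not shape) and Gram-Schmidt orthonormalized
preserving order. Coefficients are zero-mean Gaussian with standard
deviations (10, 6, 4) px scaled by image-size/128 — visible but
non-degenerate deformation of the 11–13 px canal radius. Rendering fills
the regions with smooth intensities (background 0.70, disc 0.40 shifted
by 0.08·tanh(b₀/σ₁) so texture intensity co-varies with grade, canal
0.88), smooths edges (σ 0.8), and adds band-limited texture (amplitude
0.04, smoothness 3 px) plus i.i.d. sensor noise (σ 0.02). The grade
thresholds ±0.4307·σ₁ are the tertiles of the narrowing coefficient, so
the three grades are a-priori equiprobable. All randomness derives from
one seed with counter-indexed per-instance substreams.

What the phantom does **not** emulate: MRI intensity physics and bias
fields, partial-volume effects, inter-rater annotation noise, multi-site
variation, or pathological texture beyond a linear intensity shift.
Passing tests therefore demonstrate the machinery (representation,
priors, fitters, metrics, grading) is correct and recovers known
generating parameters — not clinical-grade performance on real MRI.

## Evaluation

PtoBD is the Euclidean distance from each fitted landmark to the nearest
point of its group's ground-truth contour polyline (exact point-segment
distance via computational geometry, closed contours by default), with
landmark-to-contour groups given by index ranges (disc = outer, canal =
inner for the phantom). DSC rasterizes fitted and true polygons on the
image grid (`2·tp/(2·tp+fp+fn)`); the truth polygon must be simple, a
fitted polygon is rasterized as-is since a slightly twisted prediction is
a legitimate poor fit that still deserves a score.

## Problem sizes and defaults

The shipped experiments use M = 200 training / 50 held-out phantom
instances at 128×128, L = 3, p = 17, 4 SDM stages, 8 explicit outer
iterations, variance fractions 0.95, and 500 instances for shape-prior
recovery — sizes at which every experiment completes in minutes on one
CPU while leaving the statistical checks well-powered. Trimming defaults
to off (threshold 0) so the full multi-scale assembly is exercised;
enable it via the config when coarse redundancy matters.

## Known limitations

- 2-D, single-channel, translation-only patch motion (no per-patch
  rotation/scale warps, no occlusion handling).
- The shape prior has no rotation/scale invariance; inputs are assumed
  roughly pose-normalized (as resampled disc-plane images are).
- Subspace LK degrades when the appearance eigenspace absorbs the
  template gradient directions (little texture, strong local deformation).
- The wavelet reconstruction from patches is exact only where patches
  tile the anatomy; sparse landmark sets leave synthesis gaps.
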