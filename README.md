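# dap-anatomy — deformable appearance pyramids

A toolkit for **multi-scale, part-based representation of anatomy in 2-D
grayscale images**, aimed at landmark detection and pathology grading (the
motivating application is lumbar spinal stenosis on disc-level axial MRI).
It is for researchers who have images annotated with ordered landmark
points and want a single compact model that can *detect* those landmarks
in new images, *reconstruct* the appearance they delineate, and *classify*
the anatomy's condition from the model parameters.

## The model

A **deformable appearance pyramid (DAP)** represents an object by

- a shape **s** = [x₁, …, x_N] of N landmark positions, and
- an **appearance pyramid** 𝒜 = {A_{n,l}}, the assembly of p×p patches
  extracted at each landmark from levels l ∈ K_n of an L-level image
  pyramid (Gaussian, or wavelet with complementary octave subbands built
  by raised-cosine spectral windows whose squares tile the frequency
  plane). Patches keep the same pixel size across levels, so each level
  covers an octave-larger anatomical context. Redundant coarse patches
  can be trimmed per landmark (the scale subsets K_n).

Population variability is modelled linearly: PCA priors give
𝒜 = 𝒜̄ + P_𝒜 **b**_𝒜 for appearance and, for shape, a point-distribution
model with modes P_s and variances λ₁ ≥ … ≥ λ_t, under which a shape's
log-plausibility is −½ Σⱼ b²ⱼ/λⱼ.

Two fitters are provided:

- **Explicit (subspace Lucas–Kanade):** each patch is aligned against the
  mean-appearance template in the orthogonal complement
  𝒜⊥ = (I − P_𝒜 P_𝒜ᵀ)𝒜 of the appearance eigenspace, so learned
  population variation is not mistaken for misalignment. Every patch
  yields a prediction x̂_{n,l} with confidence σ²_{n,l}; the predictions
  and the shape prior combine into a quadratic energy whose minimizer has
  the closed form
  s = (P_sΛ⁻¹P_sᵀ + Σ_l Σ_l⁻¹)⁻¹ (P_sΛ⁻¹P_sᵀ s̄ + Σ_l Σ_l⁻¹ ŝ_l).
- **Implicit (supervised descent):** a cascade of ridge-regularized linear
  regressors Δs = R⁽ⁱ⁾ h(𝒜(s⁽ⁱ⁾)) + b⁽ⁱ⁾ maps HOG (or intensity) features
  of the appearance pyramid at the current shape to shape updates,
  starting from the mean shape at the mean location.

For classification, each fitted instance is summarized by
Φ = [**b**_s, **b**_𝒜]; a further PCA gives compact features **b**_Φ that
feed an AdaBoost ensemble (100 cycles, depth-2 trees) predicting a grade
(normal / moderate / severe) or a binary pathology label.

Because clinical MRI datasets are private, the package ships a
first-class synthetic **phantom generator**: a disc-like outer contour and
canal-like inner contour sharing 37 landmarks, deformed by a known linear
shape model whose first mode narrows the canal and drives the grade label.
Every fitter and the classifier are validated end to end on it.

## Worked example

`examples/03_sdm_landmark_detection.py` trains a wavelet DAP with a
3-stage SDM cascade on 40 phantom instances and fits 10 held-out ones:

```text
training mean landmark error per stage: ['1.92e-05', '3.91e-10', '1.01e-14']
held-out PtoBD: 0.460 px (mean-shape init: 1.188 px)
held-out DSC:   96.7 %
```

The per-stage errors show the cascade interpolating its training set; the
held-out point-to-boundary distance (mean distance from fitted landmarks
to the true contours) drops to ~0.46 px from the 1.19 px of the mean-shape
initialization, and the Dice overlap of the fitted disc and canal polygons
with the truth reaches 96.7%. The other examples cover the wavelet
pyramid round trip, the phantom generator, explicit LK fitting, grade
classification, and appearance reconstruction — each prints the quantities
it computes and a line on how to read them.

## Command line

The same pipeline is scriptable via the `dap` command:

```bash
dap synth --out data --n 50 --seed 7          # phantom dataset (PNG + PTS + labels)
dap train --data data --out model.npz --pyramid wavelet --fitter sdm
dap fit   --model model.npz --images data/images --out fits
dap eval  --pred fits --truth data --out metrics.csv   # PtoBD + DSC table
dap classify --model model.npz --data data --out grading
dap reconstruct --model model.npz --image data/images/0000.png \
                --pts fits/0000.pts --out recon.png
```

Every run writes a manifest (config + seed + versions); identical inputs
reproduce outputs bitwise.

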