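# Methods

## Problem and model

An RCM depth stack is an ordered sequence of grayscale en-face sections
acquired at fixed depth increments (`spacing_um`, default 2 µm); section
index 0 is the most superficial and depth is measured from it. The
package assumes **one anatomical stratum per section** — the labelling
convention in which each stratum begins at the first section showing its
defining feature (first honeycomb → VE, first papilla ring → DEJ, loss
of basal-layer features → PD). Under this convention a stack's labels
are monotone non-decreasing in the anatomical order SC < VE < DEJ < PD,
and the three interface depths are completely determined by the label
*counts*:

    SC/VE  = n_SC · d,   VE/DEJ = (n_SC + n_VE) · d,
    DEJ/PD = (n_SC + n_VE + n_DEJ) · d.

The counting definition is deliberately order-free: a non-monotone
*predicted* label sequence (which a per-section classifier can produce)
still yields well-defined interface depths. Real furrowed skin violates
the one-stratum assumption; mixed-strata sections are the known failure
mode, and the label reader treats non-monotone label files as a warning,
not an error.

Sections are classified independently — no smoothing across depth or
neighbouring sections. This keeps the classifier applicable to single
sections and lateral mosaics, at the cost of ignoring the strong depth
prior; the probability-depth profiles show that the prior is largely
recovered by the model anyway.

## Representation

1. **Down-sampling.** 4× per axis with Pillow's Lanczos resampling
   (truncated-sinc kernel whose support scales with the factor). The
   choice of Lanczos-3 as the concrete truncated-sinc family is a design
   decision; any kernel that suppresses content above the new Nyquist
   limit would serve. Dimensions not divisible by the factor are cropped
   to the largest multiple first.
2. **Intensity units.** Stacks are stored in [0, 1] (integer images are
   divided by their dtype maximum at load). The per-patch normalisation
   regulariser (1) and whitening ε (0.1) follow a recipe calibrated to
   8-bit intensity units, so the feature pipeline multiplies sections by
   255 (`INTENSITY_SCALE`) before patch extraction. Without this the
   regulariser would crush all patch contrast (typical [0,1] patch
   variance ≪ 1) and ε would dominate every covariance eigenvalue,
   degenerating the whitening to a scaled identity.
3. **Patch normalisation.** `(x − mean) / sqrt(var + 1)` per patch,
   population (1/N) variance. The regulariser keeps near-constant
   patches finite and suppresses amplification of sensor noise.
4. **Whitening.** Eigendecomposition of the sample covariance of the
   normalised patches; eigenvalues clipped at 0 and sorted descending;
   the energy rule keeps the smallest r with Σλ_top-r ≥ 0.95·Σλ;
   `W = V_r (Λ_r + 0.1·I)^{−1/2} V_rᵀ` (ZCA: symmetric, image-space).
   Truncation is applied before ε-regularisation. On the fit set the
   whitened covariance restricted to the retained eigenspace is exactly
   `diag(λᵢ/(λᵢ+ε))`, which the tests verify to 1e-3 Frobenius at
   50 000 patches.
5. **Dictionary.** Spherical k-means on L2-normalised whitened patches:
   assignment by maximal dot product (ties → lowest index), centroid =
   normalised sum, fixed 10 iterations, initialisation by sampling k
   distinct vectors without replacement. Empty clusters are re-seeded
   with the point farthest (lowest max-cosine) from all centroids —
   deterministic given the assignment. Zero-norm patches are assigned
   the first basis direction. The hierarchy re-clusters each node's
   members into `n_splits` children for `n_levels` levels; a node with
   fewer distinct members than `n_splits` replicates its parent centroid
   into all children, keeping the tree complete and the word count at
   exactly `n_splits^n_levels`. Quantisation is greedy root-to-leaf
   cosine descent (the hierarchy exists for speed); for a 1-level tree
   it coincides exactly with exhaustive search, and an `exhaustive`
   flag forces leaf-wide search for deeper trees.
6. **Encoding.** Dense 7×7 patches on a stride grid (stride 1 uses all
   patches; stride 2 is the default working setting here, trading a 4×
   patch reduction for no measurable accuracy loss on synthetic data),
   quantised and accumulated into a K-bin histogram, L2-normalised.
   Rotation augmentation: the section and its three right-angle
   rotations are separate training examples carrying the same label;
   at prediction their histograms are averaged and re-normalised to the
   unit sphere (re-normalisation is a design choice so train and test
   vectors live on the same sphere; it can be disabled).

## Classifier and model selection

Four binary L1-penalised logistic regressions (scikit-learn liblinear,
`l1_ratio=1`), one per stratum; probabilities are the per-class sigmoid
scores renormalised to sum to 1. The argmax label breaks exact ties in
favour of the anatomically shallowest stratum (deterministic and
documented; ties are measure-zero in practice). L1 is used because most
of a large learned vocabulary is expected to be irrelevant.

Grid search: levels {1,2,3} × splits {4,6,…,18} (the full 4–18 range by
flag) × C {10⁰…10⁵}, scored by mean pooled-section accuracy over 10
cross-validation folds **partitioned on participants** (folds are a
seeded shuffle of participant ids split into near-equal groups). The
dictionary and whitening are re-learned per fold from the fold's
training participants only — the leakage-free reading; a shared
dictionary across folds would be cheaper but lets validation
participants influence the representation. Every fit stage records the
participant ids it used (`TrainedPipeline.fit_participants`), and
`assert_no_leakage` audits any evaluation set against that record. Ties
in the grid go to the first point in (levels, splits, C) ascending
order.

The holdout utility draws a stratified-by-age-group random participant
sample, mirroring the 18-of-54 (8 young + 10 older) test-set design used
in the clinical validation of this pipeline family.

## Synthetic data

The generator emulates the four strata's en-face appearance at the
250×250 px working scale (2 µm/px), directly at that scale — the 4×
down-sampling path is exercised separately by unit tests:

* **SC** — bright, coarse, high-variance speckle (Gaussian-smoothed
  noise, grain 3–5 px), mean brighter than any other stratum.
* **VE** — honeycomb: bright borders of a jittered cell mosaic (cell
  diameter 10–14 px ≈ 20–28 µm keratinocytes) around dark interiors.
* **DEJ** — dermal papillae: dark discs (radius 8–12 px) ringed by
  bright annuli, 20–35 per field, over a honeycomb background at 0.55×
  the VE cell diameter — the basal layer's markedly smaller cells. The
  finer background is what makes DEJ separable from VE at the 7×7-patch
  scale: papilla ring edges alone are locally indistinguishable from
  honeycomb borders.
* **PD** — band-pass fibrillar noise with moderate orientation
  anisotropy (angular bandwidth 30–60°, orientation uniform per
  participant). Papillary collagen is a fine meshwork rather than
  strongly aligned fibres; narrow bandwidths additionally make the
  texture orientation-specific per participant and unlearnable from
  other participants' stacks.

Additive Gaussian pixel noise (σ = 0.05) on every section; optional
furrow artefacts overwrite a localised disc with texture from
`furrow_depth_sections` deeper, emulating mixed-strata sections.
Per-stratum thicknesses (sections): SC 6–12, VE 10–18, DEJ 8–14,
PD 8–16, drawn **per participant** together with the texture
parameters, so stacks of one participant are correlated and
participant-partitioned CV is a genuine generalisation test.

What the generator does *not* model: confocal speckle statistics,
depth-dependent signal loss, phototype-dependent reflectance, motion
artefacts, or gradual transitions between strata. Passing the
synthetic end-to-end test therefore demonstrates that the pipeline
machinery (representation, leakage-free training, prediction, interface
estimation) recovers known structure from distinguishable textures — it
does not certify clinical accuracy on real skin.

## Study conditions for the end-to-end check

20 training + 5 held-out participants, one stack each, 2-level 8-split
dictionary (64 words), C = 100, stride 2, 100 random patches per section
for dictionary learning, three seeds. These sizes keep one full run at
roughly two minutes on a single CPU; the dictionary is deliberately
smaller than the 3-level 18-split optimum reported for real skin, which
the four parametric textures do not need. Measured on held-out
participants: 100% section accuracy and 0 µm mean interface error at
seeds 1–3 (97% / 0.9 µm at a harder seed during development), against
acceptance thresholds of ≥ 90% and ≤ 6 µm.

## Numerical choices and edge cases

* Pixel → [0, 1] by dtype maximum at load; 8-bit write-out on save.
* Population (1/N) variance throughout (patch normalisation and
  covariance), matching the closed-form whitening identity.
* Eigenvalues clipped at 0 before the energy rule; ε ≥ 0 arbitrary
  (large ε degrades gracefully to a scaled projection).
* Degenerate inputs: constant patches normalise to 0; zero vectors
  quantise along the lowest-index path; k-means refuses k larger than
  the number of distinct inputs; Pearson r is reported as missing (NaN)
  when either depth series has zero variance, never as 1.
* All randomness flows through explicit seeds / numpy Generators: patch
  sampling, k-means initialisation, fold shuffling, holdout sampling and
  the synthetic generator. Everything else is deterministic, and
  re-applying a saved whitening model or dictionary is bit-reproducible.

## Known limitations

* The one-stratum-per-section assumption breaks on deeply furrowed
  skin; predictions remain usable (counting-based interfaces are
  defined for non-monotone sequences) but accuracy drops there.
* Greedy descent in a deep hierarchy is not guaranteed to find the
  globally nearest leaf; it is exact for 1-level trees and is the
  standard speed/quality trade-off of vocabulary trees.
* The CLI's stage artifacts are npz/CSV files; no provision is made for
  proprietary microscope formats, mosaics, or DICOM.
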