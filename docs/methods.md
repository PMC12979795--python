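# Methods

`mptexture` re-implements, as a tested pipeline, a texture-based
classification workflow for label-free multiphoton images of liver tissue:
three-channel field-of-view (FoV) images — CARS (red, lipid-rich
structures), TPEF (green, cellular autofluorescence), SHG (blue, fibrillar
collagen) — are split into single channels, min–max normalized, summarized
by 17 texture parameters per channel, and classified tumor vs.
non-neoplastic liver by a small feedforward network trained with full-batch
L-BFGS under strictly patient-disjoint splits. Because the tissue images the
workflow was designed for are not publicly deposited, the package ships a
synthetic cohort generator that serves as the test bed for every downstream
stage.

## Texture parameters

Each channel is min–max normalized to [0, 1] (a constant channel is flagged
degenerate and must be QC-rejected; it is never silently zeroed). The
17-parameter vector per channel is, in fixed order:

1. **First-order (5):** mean, standard deviation (n−1 denominator),
   kurtosis m4/m2² (non-excess; Gaussian → 3), skewness m3/m2^{3/2} (both on
   biased population moments), and base-2 Shannon entropy of the 256-bin
   histogram of the image re-quantized to 8 bit.
2. **Co-occurrence (12):** for each pixel distance d ∈ {1, 12, 30} (at the
   nominal 1 µm/px this is 1, 12 and 30 µm), the gray-level co-occurrence
   matrix (GLCM) is computed at orientations 0°, 45°, 90°, 135° and its
   contrast Σ P(i,j)(i−j)², correlation Σ P(i,j)(i−µᵢ)(j−µⱼ)/(σᵢσⱼ), energy
   Σ P(i,j)² and homogeneity Σ P(i,j)/(1+|i−j|) are averaged over the four
   orientations.

GLCM conventions: gray levels by uniform binning of [0, 1] into L = 8 levels
(configurable); ordered (non-symmetric) pairs by default with a symmetric
option; offsets 0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0),
135° → (−d, −d), i.e. Chebyshev distance d on the diagonals. These are the
conventions of the classic MATLAB-style `graycomatrix`; note that
scikit-image's `graycomatrix` rounds sin/cos offsets and flips the 90° sign,
so it diverges on the diagonals for d > 1 — which is why the GLCM is
computed in-package (vectorized bincount over level-pair codes) and verified
in the tests against a brute-force pair-enumeration oracle (and against
scikit-image where the conventions coincide). L and the symmetry flag are
recorded with every feature table.

Degenerate statistics (zero-variance image, zero-variance GLCM marginal)
return a sentinel 0 together with a flag rather than NaN, keeping feature
matrices finite; such images are QC-rejected upstream anyway. Whether the
original study computed first-order moments on raw 8-bit or normalized
values is not stated; this package fixes them on normalized values (all
moments except mean/sd are scale-invariant either way, and mean/sd differ
only by the fixed factor 255).

Two exact invariances follow from the construction and are enforced by
tests: rotating an image by 90° permutes the orientation set onto itself
(transposing individual GLCMs, which leaves all four properties unchanged),
so the orientation-averaged vector is invariant; and any positive affine
intensity transform upstream of min–max normalization leaves the vector
unchanged.

## Quality control

FoVs dominated by background (tissue borders, holes) or by detector
saturation are discarded before feature extraction. The rule is: reject if
any channel is constant; else if the fraction of TPEF pixels below 2/255
exceeds τ_bg = 0.25; else if the fraction of pixels saturated (255 in any
channel) exceeds τ_sat = 0.05. The source workflow states this rule only
qualitatively (it discarded 14% of images by inspection-style criteria), so
these operational thresholds are stand-ins: conservative defaults,
configurable in the run config, recorded in the manifest together with the
measured fractions and the rejection reason.

## Classifier

A fully connected network with softmax two-class head (0 = liver,
1 = tumor) is trained on standardized features (mean/sd fitted on training
data only) by minimizing cross-entropy + 0.5·λ‖W‖²/n with scipy's L-BFGS-B,
full batch, capped at 1000 iterations (the convergence criterion of the
emulated setup is the iteration cap itself; the model records whether the
cap or the gradient tolerance stopped it, plus the loss at every accepted
iterate — monotone non-increasing by the line search). Weights are
Glorot-uniform initialized from the training seed; training is bit
deterministic given data and seed.

Hyperparameters (hidden-layer count 1–3, widths {5, 10, 25, 50, 100},
activation ∈ {relu, tanh, logistic}, λ log-uniform in [1e−6, 1e−1]) are
selected by seeded random search — 100 steps by default — scored by
cross-entropy on a patient-disjoint 20% holdout of the training patients
(the emulated setup does not publish its validation scheme; patient-level
holdout is the choice consistent with the rest of the design). A
Bayesian-optimization acquisition over the same space would satisfy the same
search-history contract; random search was chosen because the acquisition
strategy only affects which candidate wins, not the pipeline semantics.

Seven models are trained per run, one per channel combination (CARS, TPEF,
SHG, CARS-TPEF, CARS-SHG, TPEF-SHG, CARS-TPEF-SHG), with input widths
17/34/51 by construction. Prediction attaches the tumor posterior, the class
call (tumor iff posterior > 0.5, strictly), and the inconclusive flag
(posterior in the **closed** band [0.3, 0.7]; the source text says "between
0.3 and 0.7" without specifying openness — closed is the documented choice,
so a posterior of exactly 0.7 is called tumor yet flagged inconclusive).

## Evaluation

ROC curves by threshold sweep with trapezoidal AUC (tie handling equals the
rank-based Mann–Whitney definition — cross-checked in tests); 2×2 confusion
matrices with correct rate, sensitivity and specificity (undefined recalls
flagged, not faked); inconclusive fraction; per-(patient, sample) tables
reporting both the misclassified fraction and the mean posterior of the true
class (two summaries that are easily conflated, so both are emitted); and
correct rates per tumor grade given an external patient → grade map, with
unknown patients grouped as "ungraded".

Border samples are rendered as posterior-probability maps on the tile grid
(missing/QC-rejected tiles masked neutral gray, inconclusive tiles hatched).
For testing, the boundary is localized as the first column whose
column-wise median posterior exceeds 0.5 — a deliberately simple,
monotone-robust estimator that is part of this package's test machinery, not
of the emulated workflow.

## Synthetic cohorts

The generator emulates, per channel, the structures that drive the real
contrast: TPEF is a stationary Gaussian-filtered white-noise field with
correlation length `cell_scale` (µm) and amplitude `cell_contrast`, carved
by dark nucleus-like voids (fixed density 40 per 10⁴ µm², radius 2–3.5 µm,
×0.35 attenuation); SHG is a near-zero background with `fiber_density`
smoothed random-walk polylines (step 3 µm, angular diffusion sd 0.25 rad,
length 40–160 µm) dilated to `fiber_thickness`; CARS is a coarser cellular
baseline plus `droplet_density` (per 10⁴ µm²) bright disks with radius in
`droplet_radius_range`. All channels receive multiplicative Gaussian noise
(`noise_scale`) and are quantized to 8 bit. Object counts are drawn by
inverse-CDF Poisson sampling from a single uniform, so raising a density
with a fixed seed adds objects to a superset — making the monotonicity
properties (mean CARS ↑ with droplet density, SHG coverage ↑ with fiber
density) exact per seed rather than only in expectation.

Reference class means at full separation (δ = 1), chosen once as
qualitatively realistic for background liver vs. ordinary HCC and not
revisited: liver `cell_scale` 4 µm / tumor 7 µm (fine parenchyma vs. thick
trabeculae), `cell_contrast` 0.45/0.65, `droplet_density` 15/5 per 10⁴ µm²
(steatosis is common in background liver), `fiber_density` 12/4 per FoV
(portal tracts vs. stroma-poor tumor), `fiber_thickness` 1.5/2 µm,
`noise_scale` 0.1. The cohort-level `class_separation` δ scales every pair
geometrically about its midpoint: δ = 0 collapses both classes onto
identical distributions (the null cohort), δ = 1 recovers the reference
sets. Per-patient variation is a multiplicative log-normal random effect
(sd 0.15 by default) drawn once per patient per parameter and applied to
both of that patient's class means — a shared patient-level effect. The
sharing matters twice: at δ = 0 it makes each patient's liver and tumor
parameters exactly identical, so the null control is a true null; and it
keeps the between-patient spread from masquerading as class signal, which
with independent per-class effects would inflate the variance of the null
AUC through patient clustering.

Seeding: one global seed expands through `numpy.random.SeedSequence` spawn
keys to per-patient seeds (independent of cohort size and generation order)
and further to per-FoV and per-structure substreams, so the whole cohort —
and any single FoV — regenerates bit-identically.

What the generator does **not** model: physical nonlinear-optics image
formation, real HCC growth patterns (trabecular/acinar/macrotrabecular),
spatially structured artefacts, channel crosstalk, vendor formats. Passing
the synthetic acceptance checks therefore demonstrates that the pipeline's
machinery is correct and patient-level generalization works when class
texture differences exist; it does not certify the accuracies reported on
real tissue, which require the original images.

## Problem sizes and numerical choices

The standard evaluation conditions used by the tests and the acceptance
script are: separated cohort of 40 patients (20 train / 20 test,
patient-disjoint), 50 FoVs per class per patient at the nominal
152 × 302 px geometry; null cohort of 20 patients (10/10 split) at δ = 0;
20 seeded border samples on a 4 × 10 grid with the true boundary at column
5. Cohort experiments use a compact search space (one hidden layer, widths
{10, 25}, relu/tanh, 4 search steps) — the full 100-step default search
space remains available in the configuration; narrowing it for the standard
runs trades search breadth for runtime and has no bearing on the properties
being checked. Training keeps the full 1000-iteration cap.

Tolerances: oracle-equivalence checks at 1e−10; exact invariances at
1e−10–1e−12; gradient check at 1e−4 against forward differences. Ties in
min–max normalization cannot occur (max > min is enforced); quantization
maps value 1.0 into the top bin.

## Known limitations

* QC thresholds are operational stand-ins for criteria the emulated study
  applied by inspection; their absolute values are untested against real
  artefact inventories.
* The synthetic generator's class contrast is, by design, much cleaner than
  real histology; correct rates near 1.0 on separated synthetic cohorts say
  nothing quantitative about performance on tissue.
* The random-search tuner explores a small space by default in cohort
  experiments; no early stopping or cross-validation beyond the single
  patient-disjoint holdout.
* Probability-map rendering is diagnostic, with no histology overlay or
  registration.
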