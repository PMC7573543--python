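# Methods

`heamlrad` re-implements, as a tested pipeline over phantom data, a radiomics
protocol for separating hepatic epithelioid angiomyolipoma (HEAML) from the
blood-rich lesions it is most often confused with — hepatocellular carcinoma
(HCC) and focal nodular hyperplasia (FNH) — on single-slice, arterial-phase
CT or MRI regions of interest. The original patient images are not publicly
available, so the package ships a synthetic cohort generator whose
class-conditional structure matches the published group summaries, and every
claim the test suite makes is about recovery of that known synthetic
structure, not about patient data.

## Phantom cohort model

Each subject is one 2-D image/mask pair plus a clinical record.

**Clinical covariates.** Sex, tumor location (left/right lobe) and
alcoholism-or-smoking are Bernoulli draws; age and maximum diameter are
Gaussian draws with redraw-truncation to positive values (diameter is also
capped at the largest lesion that fits the frame with a 2-px margin; the
truncated mass is < 0.1% at the defaults, negligible against the 3-SE
calibration checks at n = 2000). Default per-class parameters reproduce the
published per-modality group summaries: for CT, HEAML is 79% female, age
47.7 ± 10.4 y, diameter 4.4 ± 1.8 cm, 89% left lobe, 11% alcoholism/smoking;
the non-HEAML column (27% female, 45.6 ± 16.3 y, 5.3 ± 2.8 cm, 43% left,
60% habit) is realised as an enrollment-weighted HCC/FNH mixture
(78:59 for CT) with HCC male-dominant and older and FNH mostly female and
younger, the clinically expected pattern. The MRI profiles are calibrated
the same way against the MRI column (77:30 mixture).

**Lesion texture.** The mask is a filled ellipse (minor axis 0.7× the
major; the major axis in mm equals the clinical diameter to within one
pixel). Sub-resolution diameters render at a 1.6-px semi-axis floor — the
smallest ellipse guaranteed to cover at least 9 pixel centers — emulating
the partial-volume footprint of a tiny lesion without touching the drawn
covariate distribution. In-mask intensity is

    base_intensity + heterogeneity_amp * G_sigma + N(0, noise_sd)

where `G_sigma` is white noise smoothed by a Gaussian kernel of width
`correlation_length` (pixels) and renormalised analytically to unit
variance. This family was chosen because its two texture knobs map
monotonically onto the feature panel: correlation length drives NGTDM
coarseness and GLCM homogeneity, amplitude-to-noise ratio drives contrast
and first-order dispersion, giving a controllable ground truth that real
data cannot provide. The default "separable" setting renders HEAML lesions
smooth and large-amplitude against
fine-grained noisy HCC/FNH lesions (sigma 1.2–1.5 px, amplitude 10–12,
noise 10–12); base intensities differ per class and modality but cancel
under range-relative discretization, so separability is carried by texture
alone. The HEAML setting (sigma 2.1 px, amplitude 16, noise 9) was
calibrated jointly against the recovery properties the design demands of
the separable default: the texture signature must be strongly recoverable
(mean test AUC ≥ 0.9 at the CT enrollment sizes) while leaving enough
headroom that adding the clinical covariates still improves the
cross-validated fusion model in most replicates — a saturated signature
(AUC ≈ 1) would make the fusion comparison vacuous.

What the generator does **not** emulate: scanner physics, contrast
kinetics, multi-phase acquisition, lesion-shape irregularity, necrotic
cores, or any spatial covariate structure. Passing recovery tests therefore
demonstrates that the pipeline recovers a planted texture signal at the
study's sample sizes — not that the published patient-level AUCs are
reproducible.

**Default sizes.** CT cohort 33 HEAML / 78 HCC / 59 FNH, MRI 30/77/30 (the
enrollment counts), on a 64-px grid at 2.5 mm spacing so the full diameter
distribution fits the frame. Cohort-scale analyses (recovery tests, the
acceptance script) extract features at this native grid; the
spline-resampling path (default target 1×1 mm) is exercised by its own
analytic-oracle tests. All generation is a pure function of (spec,
profiles, seed), with per-subject streams spawned from the cohort seed.

## Preprocessing

3-D stacks are reduced to the slice with the largest in-mask area (ties to
the lowest index). Images are resampled by cubic B-spline interpolation on
corner-aligned grids (masks by nearest neighbour — they must stay binary);
the order-3 choice is the conventional reading of "spline interpolation".
In-mask intensities are then discretized to a fixed **bin count** of 64
equal-width bins over the observed in-mask range:

    bin(x) = floor((x - min) / (max - min) * 64) + 1,  max -> 64,

with a constant ROI mapping to level 1 everywhere and out-of-mask pixels
exactly 0. Fixed bin count (not fixed bin width) matches the protocol's
"64 bins" wording; it also makes all downstream features invariant to
affine intensity shifts, which the tests assert.

## Feature panel: 47 per channel, 9 channels, 423 total

Per channel: 7 first-order histogram statistics (mean, variance, skewness,
kurtosis, energy, entropy, uniformity — skewness/kurtosis of a constant ROI
defined 0, energy as the mean squared level so it is ROI-size invariant),
then 9 GLCM, 13 GLRLM, 13 GLSZM and 5 NGTDM features. The protocol's source
names only the family counts (7/9/13/13/5) and a handful of selected
features (coarseness, correlation, busyness, sum average, variance), so the
exact membership is fixed here from the classical definitions — Haralick
co-occurrence, Galloway/Chu/Dasarathy run-length, Thibault size-zone,
Amadasun–King gray-tone difference — with the named features included.
Matrices are 2-D, distance 1, over the four offsets (0,1),(1,0),(1,1),
(1,−1), symmetrized (GLCM) and direction-summed (GLCM/GLRLM); zones are
8-connected; NGTDM neighborhoods are the mask-restricted 3×3 ring. All
entropies are base 2. Degenerate conventions: constant-ROI GLCM correlation
= 1; NGTDM coarseness/busyness/strength denominators carry an epsilon of
1e-6, so a constant ROI has coarseness 1e6 and busyness/contrast 0. Every
matrix implementation is checked against an independent brute-force
enumeration on ≥ 100 random small ROIs.

**Wavelet channels.** A two-level *stationary* (undecimated, à trous) 2-D
Haar transform yields eight sub-bands (LL/LH/HL/HH at levels 1 and 2); each
sub-band is inverse-reconstructed alone, giving eight channel images
shape-equal to the input. A single-level 2-D transform has only four
sub-bands, so the two-level stationary scheme is the natural reading of an
"eight reconstructed images, same size as the original" protocol on
single-slice ROIs; this interpretation is load-bearing for the panel
arithmetic (8 × 47 = 376 wavelet features, 423 with the original channel)
and is recorded prominently here. Input is padded symmetrically to a
multiple of 4 and cropped back. Linearity holds exactly: the four level-1
reconstructions sum to the input, the four level-2 reconstructions sum to
the level-1 LL channel (both asserted to 1e-8). Channels are filtered on
the continuous image *before* discretization — discretizing first would
destroy the high-frequency content — and each channel is discretized
independently within the mask.

## Screening, split, balancing

The cohort splits 2:1 (train:test) stratified by group, test taking
floor(n/3) of each class so train ≥ test always. Screening ranks features
by plug-in mutual information (nats) with the binary label, each feature
discretized into 10 equal-frequency bins with duplicate quantile edges
merged — a deterministic estimator invariant to monotone feature
transforms; ties break by feature name. Top-k keeps 80 features for CT and
95 for MRI by default (the published screened counts; any k is legal on
synthetic data). SMOTE then raises the training minority (HEAML) count to
the majority count: each synthetic row is x + u(z − x), u ~ U(0,1), with z
one of x's k = 5 nearest minority neighbours (Euclidean distance on
features standardized by training mean/SD; the combination itself is taken
in the original space, so every synthetic row is an exact convex
combination of two minority originals — asserted exactly). Synthetic rows
are flagged; the test cohort is never read by screening or balancing, which
accept only the training partition.

## Signature models

RF, ridge and ANN classifiers are fit on the balanced training table,
each scoring a subject in [0, 1]: RF by class-vote fraction, "ridge
regression" as L2-penalized logistic regression (a binary-task reading that
makes its output probability-scaled and comparable), ANN as a one-hidden-
layer MLP with early stopping. Grid search is exhaustive over declared
grids (RF trees 100/300/500 × depth none/5/10; ridge penalty 10⁻³..10³ by
decade; ANN 16/64 units × L2 10⁻⁴/10⁻²), scored by stratified 5-fold CV
AUC on the training cohort, ties to the first declared point, winner refit
on the full training cohort. AUC is the tie-aware pairwise concordance
(equals the Mann–Whitney rank form; verified against O(n²) counting), with
95% confidence intervals by the DeLong structural-components variance.
Calibration curves use equal-frequency score groups (mean predicted vs
observed fraction; the groups partition subjects exactly).

## Fusion models and evaluation

The fusion stage combines the signature score with clinical covariates
(sex, age, diameter, location, habit; continuous covariates standardized,
binary 0/1) by maximum-likelihood logistic regression, fit by IRLS to
|ΔlogL| < 1e-8. Perfect separation is detected by probability saturation
and triggers a flagged ridge-1e-6 refit. AIC = 2k − 2 logL; subset
selection is exhaustive over all 2⁵ clinical subsets with the signature
score forced in (ties → fewer covariates, then lexicographic), verified
against independent re-fits. Evaluation is stratified 10-fold CV with
every choice redone inside each fold (the leakage-free reading of the
protocol): MI screening, the signature fit, and AIC selection see training
folds only, and the signature score entering the logistic stage is an
out-of-fold score from a nested inner CV (3-fold by default at these fold
sizes), so the fusion fit never sees optimistic in-bag probabilities. SMOTE
is never used on this path. Both the mean of fold AUCs and the
pooled-prediction AUC are reported (the protocol's "average AUC" is
ambiguous between them); the same folds also score two comparators — the
raw signature score and an AIC-selected clinical-only model (an
intercept-only winner scores AUC 0.5 by convention).

Decision curves report net benefit NB(t) = TP/n − FP/n · t/(1 − t) over
t = 0.01..0.99 with treat-all and treat-none references. The nomogram uses
the standard points convention: each covariate's contribution range
|β|(max − min) over its observed range, widest range = 100 points, each
scale affine in β·x with its zero at the range endpoint minimizing β·x;
total points map back through the logistic inverse, an exact round trip to
the model probability (asserted to 1e-9). Clinical two-group tables use
the tie-corrected normal-approximation Mann–Whitney U (continuous) and
Pearson chi-squared without continuity correction (categorical), p-values
floored at "<0.001" for display.

## Numerical and protocol choices that were genuinely open

- **Eight wavelet images:** two-level stationary transform (see above);
  the alternative (a 3-D eight-sub-band transform on thin stacks) was
  rejected because ROIs are explicitly single-slice.
- **MI estimator, SMOTE k, grids, ANN topology:** unstated in the source
  protocol; fixed to the conventional defaults documented above and
  declared in config/manifests.
- **AIC inside CV:** selection is redone per fold rather than once
  globally — the only reading that cannot leak test information.
- **Sub-resolution lesions:** rendered at the 1.6-px partial-volume floor
  rather than truncating the diameter distribution, which would bias the
  covariate calibration.
- **Problem sizes:** recovery experiments run at the CT enrollment counts
  on the generator's native 64-px / 2.5 mm grid; AUC-type acceptance
  quantities average 3 seeded replicates in the acceptance script and 10
  in the test suite.

## Known limitations

Phantom lesions are elliptical, stationary-texture, single-component
objects; clinical covariates are independent within subject, which real
cohorts are not; the CT/MRI distinction is a styling of intensity levels,
not physics. The published patient-level AUCs (signature 0.996/0.879 CT
train/test, 0.999/0.925 MRI; fusion 10-fold means 0.966/0.971) are not
recoverable without the original images and are used only as qualitative
guides: the structural checks (panel arithmetic, oracle equivalence,
protocol fidelity) and synthetic recovery bands are what this package can
honestly certify.
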