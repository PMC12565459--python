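# Methods

`edemagrade` implements a complete computational chain for binary glioma
grading (LGG vs HGG) from the radiomics of peritumoral edema: multimodal
MRI fusion, fused-image quality metrics, a fixed 851-feature radiomic
bank, all-relevant feature selection, and class-weighted cross-validated
classifier selection.  Because the chain is meant to be testable without
any external imaging data, its first stage is a synthetic phantom
generator whose cohorts mimic the structure of a preoperative glioma
series.  This note records the models, the parameters that matter, and
the design decisions taken where the underlying methods left choices
open.

## Synthetic phantoms

Each subject is a head ellipsoid (background exactly zero, mimicking
skull-stripping) containing a nested tumor: ellipsoidal necrotic core
(label 1) inside an enhancing shell (label 4) inside a peritumoral-edema
shell (label 2), following BraTS mask conventions.  Tumor center and
shell radii are randomized per subject within fixed ranges so cohorts
are geometrically heterogeneous.

Edema texture is a stationary Gaussian random field: white noise
smoothed with a Gaussian kernel whose sigma is the field's correlation
length, rescaled to unit variance, then scaled and shifted by the
grade's descriptor `EdemaTexture(corr_len_vox, mean_offset, variance)`.
Defaults plant a strong, detectable grade effect — LGG
(1.0 vox, 110, 144) vs HGG (2.5 vox, 140, 484) on a working intensity
scale of roughly [0, 255] — plus per-subject jitter of the edema mean
(sd 5) and additive voxel noise (sd 4).  The four weights (T1, T1Gd,
T2, FLAIR) share anatomy and edema texture but differ by fixed affine
intensity remaps and shell contrasts (edema brightest in the FLAIR-like
channel, the enhancing shell in the T1Gd-like channel), so fusion
inputs are co-registered but non-identical.

Default cohorts are 100 subjects at 81% HGG / 19% LGG on a 48x48x48
grid at 1 mm isotropic spacing; the HGG count is
`round(hgg_fraction * n_subjects)`.  Everything is reproducible from a
single seed via independent per-subject child RNG streams.

What the phantom does *not* model: MRI physics (bias fields, partial
volume, k-space artifacts), anatomical realism, or any validated
relationship between glioma grade and edema texture.  The planted
effect sizes are free parameters chosen to be clearly detectable, not
claims about real gliomas; a passing end-to-end test therefore shows
that the pipeline recovers a planted signal under the stated class
imbalance, not that it grades real tumors.

## LRD fusion

Fusion is slice-wise 2D in the axial plane.  Per slice:

1. **GDIE.**  A 3x3 maximum-local-difference (MLD) map — the maximum
   over four directions of |3*center − directional 3-pixel sum| —
   drives an adaptive detail gain.  The detail layer is the residual of
   a 3x3 mean filter; the gain interpolates linearly from `omega2`
   (0.3, weak detail) to `omega1` (1.5, strong edges) across the
   tertile interval of the nonzero MLD values.
2. **Laplacian pyramid** (Burt–Adelson, 5-tap kernel, depth `tau` = 3,
   edge replication).  EXPAND pads at the coarse scale before
   upsampling so constants are reproduced exactly; reconstruction is
   exact by construction.
3. **DGR.**  A band pixel is *significant* when |v| >= median(|band|)
   (or |v| > 0 when the median is zero — parameter-free and
   scale-invariant).  The overlapping domain is where both sources are
   significant; O + N = L exactly.
4. **Fusion rules.**  Overlap: per-pixel selection by local decision
   maximum, LDM = MLD x (3x3 local energy of |O|), ties to source A.
   Non-overlap: addition where exactly one source is significant
   (complementary information); where neither is, the locally more
   energetic source is selected instead — summing two sub-threshold
   bands would double noise.  Low bands: local-energy-maximum (LEM)
   selection with the all-ones 3x3 template.  IRS: pixels within one
   pixel of the overlap boundary are re-assigned to the level's
   globally dominant source (by summed LDM), suppressing seam
   artifacts.

A deliberate design choice: the GDIE-enhanced images drive *all*
decision maps, but the fused sub-bands are drawn from the unenhanced
pyramids.  This keeps fusion idempotent — fusing an image with itself
returns it to within round-off — while the enhancement still controls
where detail is taken from.  Feeding enhanced bands straight into the
output would re-amplify detail by up to `omega1` and make even
self-fusion diverge from its input.

Volumes are min-max rescaled to a common [0, 255] working range before
fusion; outputs are clipped back to it.  The six fused types are
T1+FLAIR, T1Gd+FLAIR, T1Gd+T1, T1Gd+T2, T2+FLAIR, T2+T1 (first-named
weight = tie-break winner A).

## Quality metrics

Entropy (256-bin histogram over [0, 255], 0–8 bits), population STD,
PSNR (peak 255; identical images report an infinite-PSNR sentinel) and
SSIM (C1 = (0.01*255)^2, C2 = (0.03*255)^2, uniform 7-wide window by
default).  PSNR/SSIM are reference-directional; since neither source
weight is canonically "the" reference for a fused image, both are
computed and stored per reference.  Cross-image-type normalization is
per-metric min-max to [0, 1]; a metric constant across types maps to 0
with a warning.

## Radiomic feature bank

851 features = 14 shape + 93 intensity/texture on the original image +
93 on each of 8 stationary-wavelet sub-bands.  Family definitions follow
the IBSI-consistent conventions of the standard radiomics feature sets;
the exact ordered name lists are pinned in `radiomics/registry.py`
(version 1.0).

* **ROI**: mask label 2 (edema); minimum 8 voxels.  No resampling by
  default (inputs are already 1 mm isotropic); volumes and masks share
  grids by contract and masks are never interpolated.
* **Discretization**: fixed bin width 25, anchored at the ROI minimum
  (`level = floor((v - min)/25) + 1`), so texture features are
  invariant to intensity shifts.
* **Shape** (mask-only): mesh volume and surface area from a
  marching-cubes surface of the zero-padded mask; sphericity
  `(36 pi V^2)^(1/3) / A`; maximum 3D diameter from the convex hull of
  surface voxels; 2D diameters per fixed-axis plane (slice = axial,
  column = coronal, row = sagittal); axis lengths `4 sqrt(lambda)` from
  the eigenvalues of the physical-coordinate covariance; elongation and
  flatness as sqrt eigenvalue ratios (0 for degenerate ROIs).
* **GLCM**: symmetric distance-1 matrices per each of the 13 unique 3D
  directions; features computed per direction and averaged (not
  matrix-merged).  Degenerate guards: correlation and MCC are 1 for a
  single gray level; a direction with no valid pairs is skipped.
* **GLRLM**: maximal runs along the 13 directions (vectorized via a
  per-direction line-id sort), per-direction features averaged.
* **GLSZM**: 26-connected zones per gray level.
* **GLDM**: dependence size = 1 + number of 26-neighbors within
  `alpha` (= 0) gray levels of the center — the center counts itself,
  so sizes start at 1.
* **NGTDM**: distance-1 neighborhood gray-tone differences; coarseness
  of a uniform ROI returns the documented sentinel 1e6 instead of
  dividing by zero.
* **Wavelet**: one-level stationary (undecimated) 3D transform,
  Coiflet-1, on the ROI bounding box; axes are edge-padded to even
  length (and to the filter length, with a warning) and cropped back,
  so every sub-band keeps the input shape and the ROI mask applies
  unchanged.  Band order LLL..HHH follows the array axes.

First-order skewness and kurtosis (non-excess) are defined as 0 for
constant ROIs.  Any non-finite feature raises with the feature's name.

## Feature selection

MinMax scaling maps each feature to [0, 1]; constant features map to 0
with a warning, and stored (min, max) bounds reproduce the transform on
held-out rows.

Boruta is implemented from scratch as a scikit-learn selector.  Per
iteration: a freshly permuted shadow copy of every feature is appended;
an XGBoost classifier is fit on [X, shadows]; a real feature scores a
*hit* when its total-gain importance exceeds the maximum shadow
importance.  Accumulated hits are tested against Binomial(t, 1/2) with
two one-sided tests at `alpha` (default 0.05), Bonferroni-corrected
within the current undecided set; features move to confirmed or
rejected, and whatever is undecided after `max_iter` (default 100,
minimum 5) is tentative.  Tentative features are excluded downstream by
default.  Shadow permutations use per-iteration child streams of the
master seed, so runs are bit-reproducible.

The importance model is deliberately *randomized and shallow*
(80 trees, depth 2, subsample 0.7, colsample_bytree 0.15).  A greedy
full-depth, full-feature booster concentrates gain on whichever column
best fits the training sample; a noise column with a lucky in-sample
correlation then beats the freshly permuted shadow maximum almost every
iteration and gets falsely confirmed.  Subsampling keeps real and
shadow importances exchangeable under the null, which is what the
binomial hit test assumes; in our simulations this configuration keeps
pure-noise cohorts clean in 19/20 replicates while recovering planted
AUC-0.8 features in 20/20.  Permutation importance is available behind
the `importance="permutation"` flag.

## Grading

Class weights are `w(c) = n / (2 n_c)` (so the weighted class masses
are equal and sum to n).  Weights enter linear models and forests via
`class_weight`, gradient boosting and naive Bayes via sample weights;
KNN and MLP have no weighting mechanism and train unweighted — a
documented limitation of those menu entries.

Evaluation: accuracy, precision, recall, F1 with HGG as the positive
class (recall = sensitivity for high-grade disease); AUC as the
Mann-Whitney rank statistic with tie-averaging (invariant under
strictly monotone score transforms); the 2x2 confusion matrix is
ordered (LGG, HGG).  Precision with no positive predictions is 0 with a
warning.

Cross-validation is stratified k-fold (default k = 10, shuffled,
seeded); k is reduced with a warning when the minority class has fewer
than k members.  Reports carry unweighted fold-mean metrics, pooled
out-of-fold metrics, the pooled confusion matrix (rows sum to true
class counts) and ROC points from pooled scores.

Model search replaces an evolutionary AutoML search with a seeded
random search over a fixed eight-entry menu (gradient boosting, random
forest, SGD, logistic regression, SVM, KNN, MLP, Bernoulli NB), each
configuration drawn from documented ranges; winner by mean CV accuracy,
ties by mean F1, then lexicographic name.  Published winning
configurations are runnable as named presets (e.g.
`paper_t1gd_flair_sgd`: SGD, alpha 0.001, eta0 0.01, elasticnet,
invscaling, power_t 0.1, l1_ratio 0.25); the one published stacked
pipeline is outside the fixed menu and is not reproduced.

## Pipeline

`run_all` chains simulate → fuse → quality → extract → select → train
for the 4 original weights and the configured fused pairs, writing
NIfTI volumes, CSV feature/metric tables and JSON reports under one run
directory.  Each stage records a hash of the configuration in
`run_state.json`; re-running with an unchanged configuration skips
completed stages.  Subjects with an empty edema ROI are excluded with a
logged reason; a missing weight skips the affected pair per subject.
One master seed fixes the phantom, Boruta, CV folds and the model
search.

## Problem sizes and numerical tolerances

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults: 100-subject cohorts at 48^3 voxels for the end-to-end
chain (~0.4 s per 851-feature extraction), 20-replicate Boruta
simulations at n = 200–300, and micro-cohorts (n = 10 at 24^3) for the
orchestration tests.  Pyramid reconstruction is exact to ~1e-13;
texture matrices match brute-force oracles exactly; first-order and
quality metrics match naive reimplementations to 1e-9.

## Known limitations

* Fusion is 2D slice-wise; no volumetric pyramids.
* The GDIE interval division and remapping are a faithful-in-spirit
  reconstruction (tertile-based piecewise-linear gain), not a published
  formula; only the stated constants omega1/omega2 and the MLD window
  are fixed by the method description.
* Shape 2D-diameter plane conventions are fixed as documented above;
  other implementations may assign slice/column/row differently.
* Wavelet sub-band numbering in third-party feature lists (".1", ".2"
  suffixes) has no published mapping; the registry order is this
  package's own.
* The phantom's grade effect is planted; results on it say nothing
  quantitative about BraTS-scale clinical performance.
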