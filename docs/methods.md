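# Methods

## The problem and the approach

Dynamic PET acquires a time-ordered stack of 3D activity volumes, so every
voxel carries a time-activity curve (TAC) rather than a single uptake value.
Standard radiomics summarizes a lesion's spatial uptake pattern on one static
image; *dynomics* extends this to the time axis.  The package implements the
full chain:

1. **Pre-processing** (`dynomics.io`): activity concentration is converted to
   standardized uptake values, SUV_bw = C[kBq/mL] · weight[g] / dose[kBq],
   assuming tissue density 1 g/mL (numerically C · weight_kg / dose_MBq).
   Decay correction is assumed to have been applied at reconstruction, so no
   decay term appears.  The *static* image is the voxelwise mean of the last
   five timeframes.  A reference-tissue VOI is obtained by reflecting the
   lesion mask across the grid midplane of the left–right axis (a pure grid
   reflection with an optional integer offset; no intensity-based
   re-centering).
2. **Feature extraction** (`dynomics.radiomics`): 107 features per VOI —
   18 first-order, 14 3D shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and
   14 GLDM — computed from scratch (definitions below).
3. **Temporal summarization** (`dynomics.temporal`): the 107 features are
   extracted independently within every timeframe, giving a frames × 107
   matrix per VOI; each feature's time course is summarized by its median
   and its median absolute deviation (MAD, unscaled — no 1.4826 Gaussian
   consistency factor, since the summary is descriptive, not a σ estimate).
   Design matrices are n × m (static, median, or mad mode) or n × 2m
   (median+mad, columns suffixed `/median`, `/mad`).
4. **Classification** (`dynomics.pipeline`): nested stratified
   cross-validation (5 outer × 5 inner folds).  Inside every training set:
   column standardization, then PCA truncated at the smallest number of
   components whose cumulative explained variance reaches 90%, then an
   XGBoost binary classifier whose maximum tree depth, minimum child weight
   and per-tree column subsample ratio are selected in the inner loop by
   mean inner-fold AUC.  All transforms are fit on training rows only and
   applied to test rows.  Metrics (AUC, accuracy, per-class
   precision/recall) are computed on the pooled out-of-fold predictions.
5. **Interpretation** (`dynomics.interpret`): exact tree-path Shapley values
   of each outer-fold model on its own held-out rows, aggregated as the mean
   absolute value per principal component; the top-ranked component is
   mapped back to its five highest-|loading| original features using a
   whole-dataset standardize+PCA computed once, for interpretation only.

## Feature definitions and numerical conventions

- **Discretization.** Default `fixed_bin_count` with 32 bins:
  level = 1 + ⌊Ng·(x−min)/(max−min)⌋ clipped to Ng; a constant region maps
  to a single level.  `fixed_bin_width` (level = ⌊x/w⌋ − ⌊min/w⌋ + 1) is
  available for parity with common radiomics defaults.  The fixed-count mode
  is the default because per-frame SUV ranges change by orders of magnitude
  over a dynamic acquisition, and relative binning makes per-frame texture
  comparable.  Each frame is discretized on its own in-mask range; a global
  scheme can be emulated by `fixed_bin_width`.
- **Aggregation.** GLCM and GLRLM build one matrix per unique 3D direction
  (13 of the 26-neighbourhood) and average features over directions; GLSZM,
  NGTDM and GLDM use a single merged matrix (their statistics have no
  direction).  Pair distances are in voxels; no mm correction is applied.
- **Degenerate cases.** 0·log 0 = 0 everywhere; Correlation = 1 and
  Skewness = Kurtosis = 0 for zero-variance input; NGTDM Busyness and
  Strength are 0 when their denominators vanish and Coarseness is capped at
  1e6 for fully homogeneous regions; a VOI with no co-occurring pair at all
  (a single voxel) degenerates to the single-level matrix P = [[1]].
  Kurtosis is the raw fourth standardized moment (a Gaussian scores ≈ 3).
  These conventions guarantee a finite 107-vector even on the near-zero
  early frames of a dynamic series.
- **Percentiles** interpolate linearly between order statistics.
- **Shape.** Mesh quantities come from a marching-cubes iso-surface at 0.5
  on the zero-padded binary mask.  Binary meshing inflates the surface of a
  digitized ball by a staircase factor, so the sphericity of a radius-8
  voxel ball is ≈ 0.92, slightly below the analytic limit of 1 — a known
  property of this (standard) surface definition, not an error.  Axis
  lengths are 4√λ of the voxel-coordinate covariance eigenvalues; 2D
  diameters are maximal pairwise distances of surface vertices projected
  onto the three coordinate planes.  Masks too small to mesh (one voxel)
  fall back to voxel-based approximations and warn.
- **GLDM.** The dependence of a voxel counts its 26-neighbours within α
  (default 0) of the center level; feature formulas weight by the dependence
  *size* j = count + 1 so that isolated voxels land in a finite j = 1
  column.  Note that a constant multi-voxel region does *not* produce a
  single-column matrix: boundary voxels have fewer in-mask neighbours than
  interior ones, so DependenceNonUniformityNormalized < 1 there by
  construction; the single-column identity holds for single-voxel VOIs.
- **Tolerances.** All texture families agree with exhaustive per-voxel
  enumeration to 1e-10, except GLCM MCC (an eigenvalue of a non-symmetric
  matrix, checked to 1e-7 because float summation order legitimately moves
  it at the 1e-9 level).

## The classification pipeline

- Standardization maps zero-variance training columns (e.g. shape features
  in MAD mode, which are structurally constant 0) to exactly 0 in both
  train and test, and flags them.
- The PCA truncation rule is "smallest k with cumulative explained-variance
  ratio ≥ threshold" (default 0.90), applied to the full eigendecomposition;
  the retained count is reported per fold.
- Hyperparameter grid (inner loop): max tree depth {2, 3, 4, 6}, min child
  weight {1, 3, 5}, column subsample ratio {0.5, 0.75, 1.0}; 100 trees at
  learning rate 0.1, `tree_method="exact"`.  Exact splits fall midway
  between consecutive training values, which matters at the small sample
  sizes this pipeline targets; histogram binning would pin thresholds to
  the edge of a class cluster.  Ties in the grid search break to the first
  point in grid order, so selection is deterministic.
- AUC is the Mann–Whitney rank statistic with average-rank tie correction;
  accuracy uses a fixed 0.5 threshold; precision/recall are reported with
  each class in turn taken as positive.
- For the tumor-vs-reference task every subject contributes two rows
  (lesion, mirrored reference); grouping by subject keeps both rows in the
  same outer fold to prevent leakage.  Plain stratification is available by
  configuration.
- Shapley values come from the boosted-tree library's exact TreeSHAP
  (`pred_contribs`); the test suite cross-checks them against a
  subset-enumeration Shapley oracle and the two-leaf stump closed form.
  PCA loading signs are normalized so each component's largest-|loading|
  entry is positive, making reruns comparable.

## The synthetic phantom

The generator (`dynomics.synthetic`) emulates a dynamic breast-FLT
acquisition: 64×64×24 grid (the full 128×128×35 matrix is available by
configuration; the smaller default keeps a cohort tractable on a desktop),
3.9×3.9×4.2 mm voxels, and the 44-frame schedule
16×5, 7×10, 5×30, 5×60, 5×180, 6×300 s.  A spherical lesion (radius 6
voxels ≈ 23 mm, a plausible locally-advanced primary) sits in one breast
position; the mirrored contralateral position provides the low-uptake
reference VOI; background tissue takes a dim uptake curve (plateau 0.5 SUV
vs 6 SUV in the lesion).  Doses are drawn uniformly from the 110–204 MBq
range and weights from a clipped normal around 70 kg; volumes are stored in
concentration units consistent with those draws so that SUV normalization
reproduces the SUV-scale construction.

Voxel TACs follow a monotone uptake model K·(1 − e^(−t/τ)) + b·t evaluated
at frame midpoints — a deliberate stand-in for compartmental kinetics,
which is out of scope (no arterial input function is modelled).  A smooth
multiplicative field (Gaussian-filtered white noise rescaled to mean 1,
CV 0.10, correlation length 2 voxels) modulates lesion amplitude in both
classes.  Gaussian noise with sd = 0.05/√(frame duration) SUV mimics
counting statistics.

The two response classes differ only in spatial-temporal structure:

- **homogeneous** (complete-responder analogue): one time constant
  (τ = 400 s) for the whole lesion;
- **heterogeneous** (partial-responder analogue): the lesion is split into
  6 seeded Voronoi subregions with time constants drawn uniformly from
  100–900 s and uptake onset delays from 0–200 s.

Subregion τ is bounded so every subregion reaches ≥ ~95% of plateau before
the static window, and each heterogeneous lesion is rescaled so its static
(last-5-frame) mean equals the homogeneous construction with the same
amplitude field *exactly*.  Static uptake level therefore carries no class
signal; what separates the classes is that the heterogeneous lesion's
spatial pattern reorganizes over the acquisition as subregions switch on
and saturate at different times.  Because per-frame fixed-bin-count
discretization is invariant to a uniform rescaling of the VOI, a noiseless
homogeneous lesion has *identical* discretized texture in every frame — its
temporal texture MAD is noise-floor only — which makes the temporal
summaries the discriminating channel by construction.

What the phantom does **not** emulate: scanner PSF and reconstruction
correlations (noise is i.i.d. Gaussian, not reconstructed Poisson),
washout/metabolite kinetics, respiratory motion, segmentation error, or
inter-scanner variability.  Passing tests therefore demonstrate that the
pipeline recovers a genuinely temporal class signal under controlled
conditions, not that it attains any particular performance on clinical
cohorts.

## Problem sizes used by the shipped checks

The test suite verifies oracle equivalence on 100 random 5×5×3 quantized
images, pipeline sanity on n = 40 (separable) and n = 200 (label-permuted)
synthetic designs, and temporal-signal recovery on three seeded cohorts of
60 subjects per class.  The acceptance script reproduces the two
classification experiments on a single 31-subject cohort (19 heterogeneous,
12 homogeneous — a realistic class imbalance for a neoadjuvant-response
cohort) and reports
pooled out-of-fold metrics for every feature mode, the retained component
count, and the top component's Shapley attribution.

## Known limitations

- Shape 2D features are not computed; the 107-feature roster is the
  standard 3D set (first-order 18 + shape3D 14 + GLCM 24 + GLRLM 16 +
  GLSZM 16 + NGTDM 5 + GLDM 14).  StandardDeviation is omitted from
  first-order in favour of Variance, per the standard 18-feature roster.
- No image resampling, resegmentation, or filtered-image (wavelet/LoG)
  features.
- The CR/PR analogy of the phantom classes is a modelling convention: the
  heterogeneous class operationalizes "subregions with distinct
  proliferative activity", not measured tumour biology.
- At n ≈ 31, nested-CV metrics have wide sampling variability; the
  acceptance script's per-mode numbers should be read with that in mind.
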