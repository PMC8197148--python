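# Methods

## Problem and pipeline

`histostack` classifies small histopathology patches (nominally 50×50 px RGB
tiles cut from H&E-stained whole-slide images) as IDC-positive or
IDC-negative using hand-crafted texture features and a stacked ensemble of
classical learners. The pipeline is:

1. **Feature extraction.** Each patch is converted to gray (BT.601 luma,
   round half away from zero) and four feature families are computed:
   256 SIFT, 256 SURF-style and 256 ORB aggregated keypoint-descriptor
   features, plus the 14 direction-averaged Haralick GLCM statistics —
   782 fused features in the fixed order [SIFT | SURF | ORB | Haralick].
2. **Stage-1 stacking.** The training partition is split into two stratified
   halves; six base learners (XGB, AB, GB, RF, ET, MLP) are fit on the first
   half and their positive-class probabilities on the second half become the
   meta-feature table (six columns).
3. **Correlation pruning.** Meta-feature columns are greedily eliminated
   while any pair has |Pearson r| > τ (default 0.95): the column with the
   largest mean |r| to the other survivors is dropped, ties broken toward
   the lower validation accuracy, then the higher column index. The kept set
   is never empty.
4. **Stage-2 meta-classifier.** Any roster learner can be the meta model;
   the boosted-tree learner GB is the default. Labels are scores thresholded
   at 0.5.

## Descriptor aggregation

Keypoint detectors return a variable number of descriptors per patch
(including zero on blank tissue), but the fused vector needs a fixed length.
The aggregation is:

* **SIFT / SURF (128-d real):** per-dimension mean concatenated with
  per-dimension population standard deviation → 256 values. Order- and
  count-invariant; with one keypoint the std half is zero.
* **ORB (256-bit binary):** descriptors are stored as 32 bytes, unpacked
  MSB-first, and aggregated as the per-bit frequency of ones → 256 values
  in [0, 1]. Bitwise negation of every descriptor complements the feature.
* **Zero keypoints → zero vector.** Such patches are kept (the table stays
  rectangular) and flagged downstream by the blank-space QC statistic
  instead of being dropped.

This aggregation is one reasonable choice among several; it is isolated
behind `aggregate_real` / `aggregate_binary` so it can be swapped.

The SIFT and ORB backends are scikit-image's implementations. The SURF slot
is served by an in-package Hessian–Haar backend: keypoints are local maxima
of the determinant of the Hessian across scales, and each keypoint is
described upright from a 16×16 window of first-order derivative responses,
4×4 subregions × 8 extended sums of dx/dy responses = 128 dimensions,
L2-normalized. It is deterministic and pure numpy/scikit-image. The family
mask also supports a 526-feature no-SURF mode.

## GLCM and Haralick statistics

Intensities are linearly binned from [0, 255] into L = 64 gray levels
(configurable; fewer levels densify the 50×50-patch co-occurrence matrix and
stabilize the eigencomputation behind the maximal correlation coefficient).
Per patch, symmetric normalized GLCMs are built at distance 1 for the four
directions 0°/45°/90°/135°; the 14 statistics are computed per direction and
averaged element-wise, which makes the vector exactly invariant under
90°-rotations and flips of square patches.

Conventions, fixed for reproducibility:

* all entropy-type statistics use log base 2 (bits); 0·log 0 ≡ 0;
* *sum variance* uses the mean of the i+j distribution (the sum average),
  treating the historical appearance of f8 in that formula as a typo;
* *variance* is Σ (i−μ)² p(i,j) with μ the marginal mean;
* IMC2 = sqrt(1 − b^(−2(HXY2 − HXY))) with b the log base, i.e. the
  exponential is taken in the same base as the entropies;
* degenerate (constant) patches give correlation = 0 and MCC = 0 rather
  than NaN, since blank tiles do occur in slide data;
* MCC is the square root of the second-largest eigenvalue of
  Q(i,j) = Σ_k p(i,k)p(j,k)/(p_x(i)p_y(k)), restricted to the support of
  the marginals.

The test suite checks all 14 statistics against an independent loop-based
evaluator (10⁻⁹ absolute; 10⁻⁶ for MCC, which goes through an eigensolver).

## Base learners

Library implementations behind one registry: XGBoost (`XGBClassifier`),
AdaBoost, gradient-boosted trees (`HistGradientBoostingClassifier`, "GB"),
random forest, extra trees, and an MLP with hidden layers (100, 50, 20, 10)
preceded by a z-score scaler fit on the MLP's own training fold (tree
learners get raw features; only the MLP is scale-sensitive, and fitting the
scaler inside the fold avoids leakage). All other hyperparameters are the
libraries' defaults, each learner seeded from the master seed via
`SeedSequence` spawn keys. No class-imbalance correction or augmentation is
applied anywhere.

Meta-features are probabilities by default because Pearson correlation on
near-binary hard labels is both coarser and noisier; `hard_labels=True`
reproduces the stricter reading where stage-1 predictions are 0/1.

## Evaluation protocol

* **Metrics:** accuracy, precision, recall, F1 from the binary confusion
  counts. Precision is 1.0 by convention when no positives are predicted
  (zero false positives); F1 is 0 when precision + recall = 0.
* **5×2cv paired t-test** (Dietterich): five replications of stratified
  two-fold CV, t = d₁⁽¹⁾ / √(Σᵢ sᵢ²/5) with 5 df, two-sided p. Both
  pipelines are refit from scratch in every fold — the test compares
  training procedures, not fitted models. The reference significance level
  is 0.05; the library reports p and leaves the decision to the caller.
* **Learning curve:** stratified subsamples of the training pool at given
  fractions, full refit per point, fixed test partition.
* **Misclassification QC:** every test error is listed with its blank-space
  fraction (share of pixels with all channels ≥ 240 or ≤ 15; both
  thresholds configurable since no pixel-level definition is standard),
  false positives first, sorted by blank-space fraction descending.

## Synthetic study conditions

The real IDC patch corpus (~278 k tiles) cannot be bundled, so the package
ships a generator whose two classes differ exactly in the second-order
statistics the pipeline targets:

* class 0 (smooth, stroma-like): Gaussian noise blurred with σ = 3 px,
  centered at 74% luminance — low GLCM contrast;
* class 1 (speckled, nucleus-dense): a correlated field (grain 1.5 px)
  thresholded into ~45% dark blobs (0.34 vs 0.84 luminance) plus jitter —
  high GLCM contrast and entropy;
* both tinted multiplicatively with an H&E-like purple (210, 170, 220) so
  the RGB→gray path is nontrivial; luminance is clipped to [0.08, 0.97],
  keeping pixel saturation ≪ 5% so the blank-space QC stays meaningful.

Defaults: 200 patches per class, 50×50 px, master seed 1. The designed
class separation is a direction-averaged GLCM contrast gap of at least 50
(observed ≈ 190 under the defaults). Each patch is a pure function of
(seed, class, index), so datasets are bit-reproducible regardless of
generation order.

What the generator does *not* emulate: nucleus/gland morphology, staining
variability, scanner noise, label noise, and the heavy class imbalance of
real slide corpora. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it detects second-order texture differences;
they do not certify real-data accuracy. The synthetic classes are much
easier to separate than IDC tissue — near-perfect synthetic accuracies are
expected and say nothing about clinical performance.

## Problem sizes and numerical choices

The shipped benchmarks use 400 patches (200 per class), an 80/20 outer
stratified split and a 50/50 inner stage-1 split; the correlation-pruning
threshold is τ = 0.95. The brute-force Haralick cross-check uses 100 random
symmetric GLCMs of size 2–8. These sizes give stable statistics while
keeping a full run in minutes on one CPU.

Tie-breaks and degeneracies are all deterministic: greedy pruning resolves
ties by validation accuracy then column index; constant meta-feature
columns get r = 0 with a warning; a τ so small that everything correlates
leaves exactly one column; stage-2 then degenerates to thresholding one
learner, which is still a valid model.

## Known limitations

* The outer train/test ratio and the descriptor aggregation scheme are
  package choices; results are reported for the shipped defaults.
* The SURF-style backend is not patent-encumbered SURF; it is a simplified
  Hessian/Haar descriptor without orientation assignment and will not match
  OpenCV SURF numerically.
* With strongly separable data the pruning threshold often removes most
  meta-features (base learners agree almost perfectly); on harder data more
  columns survive. The kept-set size is data-dependent by design.
* `scan_dataset` verifies decodability of every image up front, which is
  thorough but O(dataset); for very large corpora build the manifest once
  and reuse the CSV.
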