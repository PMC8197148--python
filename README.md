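# histostack

Texture-feature fusion and correlation-pruned stacking for classifying
breast-histopathology image patches as invasive ductal carcinoma (IDC)
positive or negative.

Pathologists grade breast cancer from H&E-stained whole-slide images that
are tiled into hundreds of thousands of small patches (nominally 50×50 px).
`histostack` is a lightweight, classical-ML alternative to deep networks for
this patch-classification task, aimed at researchers who want an
interpretable, cheap-to-train baseline: hand-crafted texture features, a
stacked ensemble of standard learners, and a statistically careful
evaluation protocol.

## Method

Per patch, four feature families are extracted from the BT.601 grayscale
image and fused in a fixed order into a 782-dimensional vector:

* **SIFT** — 128-d gradient-histogram descriptors at DoG keypoints,
  aggregated as per-dimension mean ‖ population std → 256 features;
* **SURF-style** — an in-package Hessian–Haar descriptor (det-of-Hessian
  keypoints, upright Haar-response subregions, extended 128-d), aggregated
  the same way → 256 features;
* **ORB** — 256-bit binary descriptors at FAST keypoints, aggregated as
  per-bit frequency of ones → 256 features;
* **Haralick** — 14 statistics (angular second moment, contrast,
  correlation, entropies, …) of symmetric normalized gray-level
  co-occurrence matrices P(i, j) at distance 1, averaged over the four
  directions 0°/45°/90°/135° → 14 features.

Classification is a modified stacking ensemble. The training data is split
in two stratified folds; six base learners — XGBoost (XGB), AdaBoost (AB),
gradient-boosted trees (GB), random forest (RF), extra trees (ET) and an
MLP with hidden layers (100, 50, 20, 10) — are fit on the first fold, and
their positive-class probabilities on the second fold become six
*meta-features*. Because base learners tend to agree, meta-features are
pruned by Pearson correlation: columns are greedily eliminated while any
pair has |r| > τ (default 0.95). A meta-classifier (GB by default) is then
fit on the surviving columns. Models are compared with Dietterich's 5×2cv
paired t-test,

    t = d₁⁽¹⁾ / sqrt( Σᵢ sᵢ² / 5 ),   df = 5,

where d᙮⁽ʲ⁾ are per-fold accuracy differences over five replications of
two-fold CV, with both pipelines refit from scratch in every fold.

Real IDC data (the public Kaggle breast-histopathology patch corpus) is
supported via its `0`/`1` class-directory layout, but nothing requires a
download: a bundled generator produces two-class 50×50 H&E-tinted synthetic
textures whose classes differ in second-order (GLCM) statistics, so the
whole pipeline is testable offline. See `docs/methods.md` for the model
details, conventions and limitations.

## Worked example

```python
import tempfile
from histostack import (SyntheticConfig, generate_dataset, build_table,
                        stratified_split, StackedClassifier, confusion_and_metrics)

cfg = SyntheticConfig(n_per_class=100, seed=1)
with tempfile.TemporaryDirectory() as d:
    manifest = generate_dataset(cfg, d)     # 200 PNGs in 0/ and 1/ subdirs
    table = build_table(manifest)           # SIFT+SURF+ORB+Haralick fusion
print(f"table: {len(table)} rows x {len(table.feature_names)} features")

train, test = stratified_split(table, 0.2, seed=1)
clf = StackedClassifier(seed=1)             # six learners, tau=0.95, GB meta
clf.fit(train.X, train.y)
report = confusion_and_metrics(test.y, clf.predict(test.X))
print("kept meta-features:", clf.model_.kept_names)
print(report.to_text())
```

prints

```
table: 200 rows x 782 features
kept meta-features: ['AB', 'GB']
confusion: TP=20 FP=0 FN=0 TN=20
accuracy=1.000000 precision=1.000000 recall=1.000000 f1=1.000000
```

Each row fuses 782 texture features; stage 1 yields six meta-feature
columns of which the correlation pruning keeps two here (the synthetic
classes are easy, so the learners' predictions are nearly collinear), and
the meta-classifier separates the 40 held-out patches perfectly. Synthetic
textures are far easier than real tissue — perfect synthetic accuracy
validates the machinery, not clinical performance.

The same pipeline is available from the shell:

```sh
histostack --seed 1 synth data/
histostack --seed 1 extract data/ table.csv          # 782-column CSV
histostack --seed 1 --mode standalone:SIFT extract data/ sift.csv   # 256 columns
histostack --seed 1 train table.csv model/ --report report.txt
histostack --seed 1 compare table.csv GB RF          # 5x2cv paired t-test
histostack --seed 1 learning-curve table.csv curve.csv
```

`train` prints the Pearson-correlation heatmap data of the six
meta-features, the kept subset and the confusion metrics; every command
honors `--seed` and is byte-reproducible.

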