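# thyromsi

Diagnostic classification of thyroid nodules from MALDI mass-spectrometry
imaging (MSI) of fine-needle-aspiration (FNA) needle washes.

After cytomorphology, a fifth to a third of thyroid FNAs come back
*indeterminate*, and most of those nodules turn out benign only after a
diagnostic thyroidectomy.  Pixel-resolved protein profiles acquired by
MALDI-MSI (one spectrum per 50 × 50 µm pixel, 3000–15 000 m/z, linear
positive mode) offer a molecular second opinion: benign phenotypes —
hyperplastic nodule (HP) and Hashimoto thyroiditis (HT) — and papillary
thyroid carcinoma (PTC) have distinguishable profiles.  `thyromsi`
implements the full analysis pipeline for this setting, aimed at
computational proteomics researchers who want a tested, reproducible
reference implementation:

* **synthetic cohorts** (`thyromsi.synthetic`) — no public pixel-level
  dataset of needle washes exists, so a seeded generator produces imzML
  cohorts with the structure the analysis assumes: Gaussian peak templates
  per phenotype, baseline/noise/dropout degradation, benign–malignant
  pixel mixtures, cellularity grades, and a 70-training / 170-validation
  study design;
* **I/O and data model** (`thyromsi.model`, `thyromsi.io`) — imzML 1.1 +
  ibd (continuous and processed), manifest and ROI CSVs, per-pixel
  class-map PNGs (HP green / HT yellow / PTC red);
* **preprocessing** (`thyromsi.preprocess`) — Savitzky–Golay smoothing,
  SNIP baseline subtraction, TIC normalization, MAD-based peak picking,
  and m/z binning into a feature matrix at three unit levels: single
  pixels, ROI averages, per-nodule overall averages;
* **classification** (`thyromsi.classify`) — 3-class multinomial logistic
  regression with a pure Lasso penalty; the penalty λ is chosen by
  stratified 5-fold cross-validation maximizing accuracy (ties toward the
  sparser model);
* **diagnosis** (`thyromsi.diagnose`) — per-nodule calls by overall
  average, by the "≥ 1/3 of ROIs malignant" rule, and by the
  malignant-pixel fraction against a training-derived Youden cutoff, plus
  a three-level triage with a gray zone (defaults: benign < 7.0 %, gray
  7.0–16.7 %, malignant > 16.7 %);
* **evaluation** (`thyromsi.evaluate`) — confusion counts, sensitivity /
  specificity / PPV / NPV / accuracy with exact Clopper–Pearson 95 % CIs,
  subgroup reports (borderline histologies excluded, adequate
  cellularity), the three-level cross-tab, and exploratory PCA.

`thyromsi.pipeline.run_pipeline` ties the stages together, streaming
nodules one at a time so study-scale cohorts fit in memory.

## Worked example

```python
from thyromsi.synthetic import CohortConfig
from thyromsi.pipeline import run_pipeline
from thyromsi.evaluate import subgroup_report

config = CohortConfig(
    n_hp_train=8, n_ht_train=3, n_ptc_train=5,
    validation_counts={"TIR2": 4, "TIR3": 6, "TIR4": 2, "TIR5": 4},
    pixels_per_nodule=120, mz_step=3.0, rng_seed=7,
)
result = run_pipeline(config)
print(f"selected features: {result.model.selected_features.size} of "
      f"{result.model.feature_mzs.size} bins (lambda={result.model.lambda_:.3g})")
print(f"training CV accuracy: {result.model.cv_accuracy:.3f}")
print(f"Youden cutoff: {result.youden_cutoff:.3f}")
rep = subgroup_report(result.val_diagnoses, result.manifest, "all", "call_pixel")
print(rep.summary_line())
```

prints

```
selected features: 9 of 110 bins (lambda=15.8)
training CV accuracy: 1.000
Youden cutoff: 0.150
all: TP=5 FP=0 TN=9 FN=2 | sens 71.4 (29.0-96.3) | spec 100.0 (66.4-100.0) | PPV 100.0 (47.8-100.0) | NPV 81.8 (48.2-97.7) | acc 87.5
```

The Lasso kept 9 of 110 m/z bins and separates the training ROIs
perfectly; the training-derived cutoff calls a validation nodule malignant
when more than 15 % of its pixels classify as PTC.  Both false negatives
here are poor-cellularity nodules — sparse cellular material dilutes and
attenuates the malignant signal, the pipeline's characteristic failure
mode.  Metrics print with exact binomial 95 % CIs in parentheses.

Evaluating published confusion counts directly works the same way:

```python
from thyromsi.evaluate import ConfusionCounts, diagnostic_metrics
print(diagnostic_metrics(ConfusionCounts(tp=26, fp=7, tn=31, fn=8)).summary_line())
# all: TP=26 FP=7 TN=31 FN=8 | sens 76.5 (58.8-89.3) | spec 81.6 (65.7-92.3) | PPV 78.8 (61.1-91.0) | NPV 79.5 (63.5-90.7) | acc 79.2
```

## Command line

A thin CLI mirrors the stages:

```sh
thyromsi simulate --config cohort.yaml --out cohort/ --seed 1
thyromsi inspect cohort/TR000.imzML
thyromsi preprocess --in cohort/ --out features/
thyromsi train --roi-matrix features/roi_features.csv \
               --labels features/roi_labels.csv --folds 5 --seed 1 --out model.json
thyromsi classify --model model.json --cohort cohort/ --out diag.csv
thyromsi evaluate --diag diag.csv --manifest cohort/manifest.csv --out report/
```

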