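# Methods

## Problem and model

`thyromsi` implements an in-silico version of a cytomolecular diagnostic
pipeline for thyroid nodules sampled by fine-needle aspiration (FNA).  A
MALDI mass-spectrometry-imaging acquisition yields one protein-profile mass
spectrum per 50 × 50 µm raster pixel over the 3000–15 000 m/z range (linear
positive mode).  Three spectral phenotypes are modelled: hyperplastic
nodule (HP) and Hashimoto thyroiditis (HT), both benign, and papillary
thyroid carcinoma (PTC), malignant.

The statistical core is a multinomial logistic regression with a pure L1
(Lasso) penalty fit on ROI-average peak-feature spectra of a training
cohort.  Let x be the standardized feature vector of one analysis unit and
(β_k, β0_k) the class coefficients; class probabilities are the softmax of
the three linear scores.  The penalty λ is selected by stratified 5-fold
cross-validation maximizing mean accuracy, with ties resolved toward the
larger λ (sparser model).  Class imbalance in the ROI labels is
deliberately left unweighted.

Per-nodule diagnosis aggregates unit-level calls three ways:

1. **overall average** — argmax class of the nodule's mean spectrum,
   mapped to benign (HP, HT) or malignant (PTC);
2. **ROI rule** — malignant iff at least one third of the nodule's ROIs
   are called PTC (inclusive bound);
3. **pixel rule** — malignant iff the malignant-pixel fraction strictly
   exceeds a cutoff estimated on the training set by maximizing the Youden
   index J = sensitivity + specificity − 1.

On top of the binary pixel rule sits a three-level triage: fractions below
a low cutoff are benign, above the high cutoff malignant, and the closed
band in between is a *gray zone* triaged to follow-up.  The defaults are
7.0 % and 16.7 %; the pipeline re-derives both from the training fractions
(see *Cutoff estimation*).

## Preprocessing

Each pixel spectrum passes through: trim to the acquisition range →
Savitzky–Golay smoothing (half-window 10, cubic) → SNIP baseline
subtraction (100 iterations, increasing window, clamped at zero) → TIC
normalization (intensities sum to one).  Pixels that are empty after
trimming or have zero total ion current are excluded and counted; fraction
denominators use retained pixels only, since uninformative pixels would
otherwise dilute the malignant fraction.

Peaks are positive local maxima whose robust z-score — deviation from the
spectrum median over a 1.4826·MAD noise scale — reaches the SNR threshold
(default 3).  The z-score form matters because SNIP-and-clamp leaves a
small positive background offset that a raw intensity/MAD ratio would
mistake for signal.  Peaks are binned on the m/z axis by single-linkage
clustering with a relative gap tolerance of 0.002; each bin's
representative m/z is the intensity-weighted mean.  Bins are learned once,
from training ROI-average peaks, and frozen for every other unit (pixels,
overall averages, validation cohorts), so the validation set never leaks
into the feature axis.

Preprocessing is not exactly idempotent: smoothing and SNIP are
contractive maps, and a second pass changes a clean spectrum at the
few-percent level (≈5 % relative L2 on noiseless two-Gaussian fixtures).
Trim and TIC renormalization are exactly idempotent.  The test suite
asserts these measured properties rather than an unattainable fixed-point
identity.

## Cutoff estimation

Candidate cutoffs are midpoints between consecutive distinct training
fractions plus sentinels outside the observed range, which makes the
strict-inequality decision rule unambiguous at observed values.  The
Youden cutoff is the smallest candidate maximizing J.  The double cutoff
for the gray zone is estimated as: high = smallest candidate making the
rule "malignant iff fraction > high" maximally specific; low = largest
candidate ≤ high making "benign iff fraction < low" maximally sensitive.
`low == high` (empty gray zone) is permitted.  "Maximizing sensitivity and
specificity" admits several operationalizations; this lexicographic rule
is deterministic, reproduces the obvious answers on separated data, and
degrades gracefully (the gray zone spans the whole range when the classes
are indistinguishable).  The binary pixel rule uses the Youden cutoff as
its high threshold — the same value serves as the upper triage bound, with
the double-cutoff low bound clipped to not exceed it.

## Evaluation

Malignant is the positive class.  Sensitivity, specificity, PPV, NPV and
accuracy come with exact Clopper–Pearson 95 % intervals in the
beta-quantile form: lower = Beta(α/2; k, n−k+1), upper =
Beta(1−α/2; k+1, n−k), with the conventional 0 and 1 at k = 0 and k = n.
Zero-denominator metrics are reported as explicitly undefined, never 0.
Printed percentages are rounded half-up at two decimals and then half-up
again to one decimal — the two-stage scheme of spreadsheet-style clinical
tables (it prints 30/38 as 79.0 where one-stage rounding would give 78.9).

Subgroup reports compose named filters: excluding borderline histologies
(NIFTP, follicular adenoma, WDT-UMP), restricting to adequate cellularity
(good/optimal), and restricting to indeterminate cytology (TIR3/TIR4).
The three-level cross-tab tabulates truth subtype × {benign, gray,
malignant}; agreement for a truth group may count gray-zone cases as
agreement, since those are triaged to follow-up rather than miscalled.

The exploratory PCA runs on centered, unit-variance columns (n−1
covariance); zero-variance columns are dropped with a warning and all
positive-eigenvalue components are returned.

## Synthetic cohorts

No public pixel-level dataset of FNA needle washes exists, so a generator
produces cohorts with the statistical structure the analysis assumes.

**Templates.**  Each phenotype is a set of Gaussian peaks (default 10 per
class) at distinct m/z positions with heights uniform in [40, 100]
(arbitrary counts) and widths σ = 2 Da · m/z / 5000, a linear-mode-like
broadening.  A configurable fraction of peaks is shared by all classes,
plus an extra block shared only by HP and HT, making the benign classes
spectrally closer to each other than to PTC.  Each class always keeps at
least one unique peak unless the separability guarantee is switched off.

**Noise.**  Per pixel: an exponential baseline (amplitude 25, decay
5·10⁻⁴ Da⁻¹), additive half-normal detector noise (σ = 16), multiplicative
height jitter (CV 0.3) and per-peak dropout (probability 0.15).  These
defaults put single-pixel peaks at a raw SNR of roughly 3–6 on
full-content samples — clean enough that adequate-cellularity pixels
classify almost perfectly (benign nodules show ≈2 % misclassified pixels),
noisy enough that attenuated spectra genuinely lose peaks.

**Cellularity.**  The semi-quantitative grades map to the fraction of
informative (template-bearing) pixels, drawn uniformly per nodule from
poor 0.20–0.30, good 0.30–0.70, optimal 0.70–1.00.  Template amplitudes
additionally scale linearly with that fraction — sparsely cellular samples
yield low-signal spectra even on their informative pixels, while the
instrument noise floor stays fixed.  This is the false-negative mechanism:
poor samples both dilute the malignant-pixel fraction with background
pixels and lose per-pixel detection.  Remaining pixels are background-only
(baseline + noise).

**Nodules and ROIs.**  Pixels sit on a near-square raster (1-based imzML
coordinates); informative pixels are assigned to phenotypes in contiguous
row-major runs per the requested composition (largest-remainder rounding).
ROIs are axis-aligned single-class rectangles carved from complete raster
rows inside a class's run (height-1 segments when a run holds no complete
row), covering about half of each class's pixels, with the per-nodule ROI
budget split across classes proportionally.

**Cohort design.**  The default design is a two-stage study: 70
adequate-cellularity training nodules (40 HP + 10 HT benign TIR2, 20 PTC
malignant TIR5) and 170 validation nodules split 33/77/19/41 across
TIR2–TIR5, with 105 benign / 65 malignant truth labels, 29 borderline
histologies, and an adequate-cellularity subset of 72 split 17/23/9/23
across tiers.  Malignant nodules carry a 90 % malignant-pixel composition,
borderline nodules a 10 % admixture (their profiles straddle both groups);
medullary carcinoma is represented with the malignant phenotype.  Setting
a concrete `cellularity_grade` forces it on every validation sample, which
is how quality degradation is studied on otherwise identical seeds.
Randomness is hierarchical — each nodule draws from a stream keyed on
(cohort seed, design index) — so cohorts are exactly reproducible and
subsets can be re-simulated in isolation.

**What the generator does not emulate.**  Blood/hemoglobin interference
chemistry, lymph-node and parathyroid phenotypes, mass-calibration drift,
spatial autocorrelation of noise, and realistic spot geometry are all
absent; background pixels are spectrally featureless rather than carrying
inflammatory or stromal signatures.  Passing tests therefore demonstrate
that the statistical machinery behaves correctly under its stated
assumptions, not that the classifier would reach any particular
performance on real needle washes.

## Problem sizes and numerical choices

Study-scale runs (tests and the acceptance script) use 500 pixels per
nodule on a 2 Da grid — 120 000 pixel spectra over 240 nodules — which
preserves every structural property of the analysis while keeping a full
two-cohort run in the minutes range on one CPU; the library default is
1000 pixels per nodule on a 1 Da grid.  SNIP runs in single precision
(the baseline is subtracted and clamped, so ~10⁻⁷ relative error is
inconsequential).  The L1 multinomial fit uses scikit-learn's saga solver
(tolerance 10⁻³, up to 1000 epochs, seeded): accuracy-based CV selection
is insensitive to the last decimals of the coefficients, and the looser
tolerance keeps a 16-point λ path over 5 folds in seconds.  λ is the
inverse of scikit-learn's C.  Probability ties in the argmax call break toward
PTC > HT > HP so a tie never silently favors benign.  Exact-tie detection
in cutoff and λ selection uses a 10⁻¹² tolerance.  Constant features are
dropped (with a warning) before standardization; an all-zero feature row
predicts from the effective intercepts alone.

## Known limitations

* The ROI rule flags borderline-admixture nodules as malignant whenever a
  malignant ROI is annotated — with ≤ 3 ROIs any annotated malignant
  region reaches the one-third bound.  This mirrors clinical false
  positives on follicular adenomas but means the ROI rule's specificity
  depends on the ROI budget.
* The Youden cutoff inherits the training cohort's worst malignant
  fraction; with few malignant training samples it is high-variance.
* The λ grid is fixed (log-spaced 10⁻³…10¹·⁵); data far outside the
  standardized scale assumed here may need a wider grid.
* `pca_explore` is exploratory only; nothing downstream consumes it.
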