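"""End-to-end orchestration of the synthetic-cohort analysis.

The pipeline streams nodules one at a time (simulate -> preprocess ->
reduce to peak lists), learns the feature bins and the Lasso multinomial
model on the training ROI-average spectra, estimates the pixel-fraction
cutoffs on the training set (Youden index for the binary rule, double
cutoff for the gray-zone band), and then diagnoses every nodule in both
sets with all three aggregation rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from thyromsi.classify import ClassifierModel, classify_units, fit_lasso_multinomial
from thyromsi.diagnose import (
    DiagnosisThresholds,
    derive_double_cutoff,
    derive_youden_cutoff,
    diagnose_nodule,
)
from thyromsi.model import CohortManifest
from thyromsi.preprocess import (
    FeatureMatrix,
    PeakBins,
    PreprocessConfig,
    SampleFeatures,
    assemble_matrices,
    extract_sample_features,
)
from thyromsi.synthetic import CohortConfig, iter_cohort, make_class_templates


@dataclass
class PipelineResult:
    model: ClassifierModel
    bins: PeakBins
    youden_cutoff: float
    double_cutoff: tuple
    thresholds: DiagnosisThresholds
    train_diagnoses: pd.DataFrame
    val_diagnoses: pd.DataFrame
    manifest: pd.DataFrame
    pixel_accuracy: dict
    train_features: list = field(default_factory=list, repr=False)

    @property
    def diagnoses(self) -> pd.DataFrame:
        return pd.concat([self.train_diagnoses, self.val_diagnoses], ignore_index=True)


def featurize_cohort(
    config: CohortConfig,
    pre_cfg: PreprocessConfig,
    subset: str = "all",
) -> list[SampleFeatures]:
    """Simulate and preprocess a cohort subset, keeping only peak lists."""
    templates = make_class_templates(
        config.rng_seed, config.n_peaks_per_class, config.shared_peak_fraction
    )
    return [
        extract_sample_features(sample, pre_cfg)
        for sample in iter_cohort(config, templates=templates, subset=subset)
    ]


def _per_sample_calls(
    model: ClassifierModel,
    feats: Sequence[SampleFeatures],
    pixel_fm: FeatureMatrix,
    roi_fm: FeatureMatrix,
    overall_fm: FeatureMatrix,
) -> tuple[dict, dict, dict, dict]:
    pixel_calls = classify_units(model, pixel_fm) if pixel_fm.n_units else []
    roi_calls = classify_units(model, roi_fm) if roi_fm.n_units else []
    overall_calls = classify_units(model, overall_fm) if overall_fm.n_units else []

    pix_by, roi_by, ov_by, acc_by = {}, {}, {}, {}
    i = j = 0
    for k, f in enumerate(feats):
        n_pix, n_roi = len(f.pixel_ids), len(f.roi_ids)
        calls = pixel_calls[i: i + n_pix]
        pix_by[f.sample_id] = calls
        roi_by[f.sample_id] = roi_calls[j: j + n_roi]
        ov_by[f.sample_id] = overall_calls[k] if f.n_pixels_retained > 0 else None
        if f.pixel_truth is not None:
            pairs = [
                (c, t) for c, t in zip(calls, f.pixel_truth) if t is not None
            ]
            acc_by[f.sample_id] = (
                float(np.mean([c == t for c, t in pairs])) if pairs else float("nan")
            )
        i += n_pix
        j += n_roi
    return pix_by, roi_by, ov_by, acc_by


def _diagnose_set(
    feats: Sequence[SampleFeatures],
    pix_by: dict,
    roi_by: dict,
    ov_by: dict,
    thresholds: DiagnosisThresholds,
    dataset: str,
) -> pd.DataFrame:
    rows = []
    for f in feats:
        d = diagnose_nodule(
            f.sample_id,
            ov_by[f.sample_id],
            roi_by[f.sample_id],
            pix_by[f.sample_id],
            thresholds,
        )
        rows.append(
            {
                "sample_id": d.sample_id,
                "dataset": dataset,
                "n_pixels_classified": d.n_pixels_classified,
                "malignant_pixel_fraction": d.malignant_pixel_fraction,
                "roi_malignant_fraction": d.roi_malignant_fraction,
                "call_overall_avg": d.call_overall_avg,
                "call_roi": d.call_roi,
                "call_pixel": d.call_pixel,
                "call_three_level": d.call_three_level,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: CohortConfig,
    pre_cfg: Optional[PreprocessConfig] = None,
    cv_folds: int = 5,
    thresholds: Optional[DiagnosisThresholds] = None,
    training_features: Optional[list] = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic cohort.

    When ``thresholds`` is None the pixel cutoffs are derived from the
    training set (Youden index for the binary high cutoff; the double
    cutoff supplies the gray-zone lower bound).  ``training_features`` can
    reuse the featurized training set from a previous run whose config
    shares the training design and seed (e.g. cellularity-variant runs).
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    from thyromsi.synthetic import cohort_design

    manifest = cohort_design(config)
    train_feats = (
        training_features
        if training_features is not None
        else featurize_cohort(config, pre_cfg, subset="training")
    )
    val_feats = featurize_cohort(config, pre_cfg, subset="validation")

    pix_tr, roi_tr, ov_tr, bins, meta_tr = assemble_matrices(train_feats, pre_cfg)
    model = fit_lasso_multinomial(
        roi_tr, meta_tr["roi_labels"], cv_folds=cv_folds, rng_seed=config.rng_seed
    )

    tr_pix, tr_roi, tr_ov, tr_acc = _per_sample_calls(
        model, train_feats, pix_tr, roi_tr, ov_tr
    )

    # training malignant-pixel fractions -> cutoffs
    truth = {r.sample_id: r.truth_label for r in manifest}
    fracs, labels = [], []
    for f in train_feats:
        calls = tr_pix[f.sample_id]
        if calls:
            fracs.append(sum(c == "PTC" for c in calls) / len(calls))
            labels.append(truth[f.sample_id])
    if thresholds is None:
        youden = derive_youden_cutoff(fracs, labels)
        low, high = derive_double_cutoff(fracs, labels)
        thresholds = DiagnosisThresholds(
            pixel_cutoff_high=youden,
            pixel_cutoff_low=min(low, youden),
        )
        double = (low, high)
    else:
        youden = thresholds.pixel_cutoff_high
        double = (thresholds.pixel_cutoff_low, thresholds.pixel_cutoff_high)

    pix_va, roi_va, ov_va, bins2, _ = assemble_matrices(val_feats, pre_cfg, bins=bins)
    va_pix, va_roi, va_ov, va_acc = _per_sample_calls(
        model, val_feats, pix_va, roi_va, ov_va
    )

    train_df = _diagnose_set(train_feats, tr_pix, tr_roi, tr_ov, thresholds, "training")
    val_df = _diagnose_set(val_feats, va_pix, va_roi, va_ov, thresholds, "validation")

    def _mean_acc(accs: dict) -> float:
        vals = [v for v in accs.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return PipelineResult(
        model=model,
        bins=bins,
        youden_cutoff=youden,
        double_cutoff=double,
        thresholds=thresholds,
        train_diagnoses=train_df,
        val_diagnoses=val_df,
        manifest=manifest.to_frame(),
        pixel_accuracy={
            "training": _mean_acc(tr_acc),
            "validation": _mean_acc(va_acc),
            "per_sample_training": tr_acc,
            "per_sample_validation": va_acc,
        },
        train_features=list(train_feats),
    )
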