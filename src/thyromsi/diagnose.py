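"""Per-nodule diagnosis: aggregation rules, cutoffs and gray-zone triage.

A nodule's binary call (benign vs malignant) can be derived three ways:
(1) the class with the highest probability on the overall-average spectrum,
(2) at least one third of ROIs classified as malignant (inclusive bound),
(3) the malignant-pixel fraction strictly above a cutoff estimated on the
training set by the Youden index.  On top of the binary rule sits a
three-level triage of the malignant-pixel fraction: benign below the low
cutoff, malignant above the high cutoff, and a gray zone (closed band)
in between that is triaged to follow-up rather than called.  Default
cutoffs: 7.0% (low) and 16.7% (high).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from thyromsi.errors import ParameterError
from thyromsi.model import BENIGN_CLASSES

INADEQUATE = "inadequate"


@dataclass(frozen=True)
class DiagnosisThresholds:
    pixel_cutoff_high: float = 0.167
    pixel_cutoff_low: float = 0.070
    roi_cutoff: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pixel_cutoff_low <= self.pixel_cutoff_high <= 1.0:
            raise ParameterError(
                "cutoffs must satisfy 0 <= low <= high <= 1 "
                f"(got low={self.pixel_cutoff_low}, high={self.pixel_cutoff_high})"
            )
        if not 0.0 < self.roi_cutoff <= 1.0:
            raise ParameterError("roi_cutoff must lie in (0, 1]")


@dataclass
class DiagnosisResult:
    sample_id: str
    malignant_pixel_fraction: float
    n_pixels_classified: int
    roi_malignant_fraction: float
    call_overall_avg: str
    call_roi: str
    call_pixel: str
    call_three_level: str


def class_to_binary(label: str) -> str:
    """Map a phenotype call to the per-nodule binary vocabulary."""
    return "benign" if label in BENIGN_CLASSES else "malignant"


def diagnose_overall_average(class_call: str) -> str:
    """Binary call from the overall-average spectrum's argmax class."""
    return class_to_binary(class_call)


def diagnose_by_rois(roi_calls: Sequence[str], roi_cutoff: float = 1.0 / 3.0) -> str:
    """Malignant iff at least ``roi_cutoff`` of the ROIs are called PTC."""
    if not roi_calls:
        return INADEQUATE
    frac = sum(c == "PTC" for c in roi_calls) / len(roi_calls)
    return "malignant" if frac >= roi_cutoff else "benign"


def diagnose_pixelwise(
    pixel_calls: Sequence[str], pixel_cutoff_high: float = 0.167
) -> tuple[float, str]:
    """(malignant-pixel fraction, call); malignant iff strictly above cutoff."""
    if not pixel_calls:
        return float("nan"), INADEQUATE
    frac = sum(c == "PTC" for c in pixel_calls) / len(pixel_calls)
    return frac, ("malignant" if frac > pixel_cutoff_high else "benign")


def diagnose_three_level(fraction: float, low: float = 0.070, high: float = 0.167) -> str:
    """Three-level triage: benign (< low), gray ([low, high]), malignant (> high)."""
    if low > high:
        raise ParameterError(f"low cutoff {low} exceeds high cutoff {high}")
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < low:
        return "benign"
    if fraction > high:
        return "malignant"
    return "gray"


# ---------------------------------------------------------------------------
# Cutoff estimation on the training set
# ---------------------------------------------------------------------------

def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values plus outer sentinels.

    Midpoint candidates make the strict-> decision rule unambiguous at the
    observed values themselves.
    """
    v = np.unique(values)
    delta = (np.diff(v).min() / 2.0) if v.size > 1 else 0.01
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - delta], mids, [v[-1] + delta]])


def _split_by_truth(
    fractions: Sequence[float], truth_labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    fr = np.asarray(fractions, dtype=float)
    tr = np.asarray(truth_labels)
    if fr.size != tr.size or fr.size == 0:
        raise ParameterError("fractions and truth labels must align and be nonempty")
    bad = set(tr) - {"benign", "malignant"}
    if bad:
        raise ParameterError(f"unknown truth label {sorted(bad)[0]!r}")
    ben = fr[tr == "benign"]
    mal = fr[tr == "malignant"]
    if ben.size == 0 or mal.size == 0:
        raise ParameterError("both truth classes must be present to estimate a cutoff")
    return ben, mal


def derive_youden_cutoff(
    fractions: Sequence[float], truth_labels: Sequence[str]
) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1 under strict >.

    Candidates are midpoints between consecutive distinct observed fractions
    plus sentinels outside the range; ties return the smallest maximizer.
    """
    ben, mal = _split_by_truth(fractions, truth_labels)
    cands = _candidate_cutoffs(np.concatenate([ben, mal]))
    best_c, best_j = None, -np.inf
    for c in cands:
        j = np.mean(mal > c) + np.mean(ben <= c) - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c


def derive_double_cutoff(
    fractions: Sequence[float], truth_labels: Sequence[str]
) -> tuple[float, float]:
    """Estimate the (low, high) gray-zone cutoffs on training fractions.

    The high cutoff makes the rule "malignant iff fraction > high" maximally
    specific, taking the smallest such candidate (most sensitive among the
    maximally specific ones).  The low cutoff makes "benign iff fraction <
    low" maximally sensitive -- i.e. it leaves as few malignant nodules as
    possible below it -- taking the largest such candidate not exceeding
    high.  ``low == high`` (empty gray zone) is allowed.
    """
    ben, mal = _split_by_truth(fractions, truth_labels)
    cands = _candidate_cutoffs(np.concatenate([ben, mal]))

    spec = np.array([np.mean(ben <= c) for c in cands])
    hi_idx = int(np.flatnonzero(spec >= spec.max() - 1e-12)[0])
    high = float(cands[hi_idx])

    lo_cands = cands[cands <= high + 1e-15]
    sens = np.array([np.mean(mal >= c) for c in lo_cands])
    lo_idx = int(np.flatnonzero(sens >= sens.max() - 1e-12)[-1])
    low = float(lo_cands[lo_idx])
    return low, high


# ---------------------------------------------------------------------------
# Combined per-nodule result
# ---------------------------------------------------------------------------

def diagnose_nodule(
    sample_id: str,
    overall_class_call: Optional[str],
    roi_calls: Sequence[str],
    pixel_calls: Sequence[str],
    thresholds: DiagnosisThresholds = DiagnosisThresholds(),
) -> DiagnosisResult:
    """Apply all three aggregation rules plus the three-level triage."""
    frac, call_pixel = diagnose_pixelwise(pixel_calls, thresholds.pixel_cutoff_high)
    call_roi = diagnose_by_rois(roi_calls, thresholds.roi_cutoff)
    call_overall = (
        diagnose_overall_average(overall_class_call)
        if overall_class_call is not None
        else INADEQUATE
    )
    roi_frac = (
        sum(c == "PTC" for c in roi_calls) / len(roi_calls) if roi_calls else float("nan")
    )
    if np.isnan(frac):
        three = INADEQUATE
    else:
        three = diagnose_three_level(
            frac, thresholds.pixel_cutoff_low, thresholds.pixel_cutoff_high
        )
    return DiagnosisResult(
        sample_id=sample_id,
        malignant_pixel_fraction=frac,
        n_pixels_classified=len(pixel_calls),
        roi_malignant_fraction=roi_frac,
        call_overall_avg=call_overall,
        call_roi=call_roi,
        call_pixel=call_pixel,
        call_three_level=three,
    )
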