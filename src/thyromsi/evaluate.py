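"""Diagnostic-performance evaluation: confusion counts, exact CIs, subgroup
reports, gray-zone cross-tabulation, and exploratory PCA.

Malignant is the positive class throughout.  Confidence intervals are exact
Clopper-Pearson (beta-quantile form) at 95% by default.  Zero-denominator
metrics surface as explicit ``None`` ("undefined"), never as 0 or silent
NaN.  Printed percentages follow the clinical-report convention of the
source tables: values are rounded half-up at two decimals and the rounded
value is rounded half-up again to one decimal (so e.g. 78.947 prints as
79.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from thyromsi.errors import ParameterError

BORDERLINE_SUBTYPES = frozenset({"NIFTP", "FA", "WDT-UMP"})
ADEQUATE_GRADES = frozenset({"good", "optimal"})


# ---------------------------------------------------------------------------
# Rounding / formatting
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal("1." + "0" * decimals) if decimals > 0 else Decimal("1")
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def printed_percent(fraction: float) -> float:
    """Percentage as printed in the report tables (two-stage half-up)."""
    return round_half_up(round_half_up(100.0 * fraction, 2), 1)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ParameterError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: Sequence[str], truth: Sequence[str]) -> ConfusionCounts:
    """Tabulate binary calls against truth (malignant positive).

    Gray-zone or inadequate calls must be resolved (or dropped) by the
    caller before tabulation.
    """
    if len(pred) != len(truth) or len(pred) == 0:
        raise ParameterError("pred and truth must be nonempty and aligned")
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if t not in ("benign", "malignant"):
            raise ParameterError(f"unknown truth label {t!r}")
        if p not in ("benign", "malignant"):
            raise ParameterError(f"unresolved prediction {p!r}")
        if t == "malignant":
            tp += p == "malignant"
            fn += p == "benign"
        else:
            tn += p == "benign"
            fp += p == "malignant"
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial CI via the beta-quantile formulation."""
    if not (0 <= k <= n) or n < 1:
        raise ParameterError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ParameterError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


@dataclass
class PerformanceReport:
    """Point metrics with exact CIs; ``None`` marks an undefined metric."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]
    ci_sensitivity: Optional[tuple] = None
    ci_specificity: Optional[tuple] = None
    ci_ppv: Optional[tuple] = None
    ci_npv: Optional[tuple] = None
    subgroup: str = ""

    def printed(self) -> dict:
        """Metrics as printed percentages (None stays undefined)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[name] = None if v is None else printed_percent(v)
        return out

    def summary_line(self) -> str:
        def pct(v, ci):
            if v is None:
                return "undefined"
            s = f"{printed_percent(v):.1f}"
            if ci is not None:
                s += f" ({printed_percent(ci[0]):.1f}-{printed_percent(ci[1]):.1f})"
            return s

        c = self.counts
        return (
            f"{self.subgroup or 'all'}: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn} | "
            f"sens {pct(self.sensitivity, self.ci_sensitivity)} | "
            f"spec {pct(self.specificity, self.ci_specificity)} | "
            f"PPV {pct(self.ppv, self.ci_ppv)} | "
            f"NPV {pct(self.npv, self.ci_npv)} | "
            f"acc {pct(self.accuracy, None)}"
        )


def diagnostic_metrics(
    counts: ConfusionCounts, level: float = 0.95, subgroup: str = ""
) -> PerformanceReport:
    """Sensitivity/specificity/PPV/NPV/accuracy with exact binomial CIs."""

    def ratio(k: int, n: int):
        if n == 0:
            return None, None
        return k / n, exact_binomial_ci(k, n, level)

    sens, ci_sens = ratio(counts.tp, counts.tp + counts.fn)
    spec, ci_spec = ratio(counts.tn, counts.tn + counts.fp)
    ppv, ci_ppv = ratio(counts.tp, counts.tp + counts.fp)
    npv, ci_npv = ratio(counts.tn, counts.tn + counts.fn)
    acc = (counts.tp + counts.tn) / counts.total
    return PerformanceReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        ci_ppv=ci_ppv,
        ci_npv=ci_npv,
        subgroup=subgroup,
    )


# ---------------------------------------------------------------------------
# Subgroups and cross-tabulation
# ---------------------------------------------------------------------------

def filter_subgroup(df: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    """Apply a named subgroup filter to a diagnoses+manifest frame.

    ``all`` keeps everything; ``borderline_excluded`` removes borderline
    histologies (NIFTP, FA, WDT-UMP); ``adequate`` keeps good/optimal
    cellularity; ``indeterminate`` keeps TIR3/TIR4 cytology.  Filters
    compose with '+' (e.g. ``adequate+indeterminate``).
    """
    out = df
    for part in subgroup.split("+"):
        part = part.strip()
        if part in ("", "all"):
            continue
        elif part == "borderline_excluded":
            out = out[~out["subtype"].isin(BORDERLINE_SUBTYPES)]
        elif part == "adequate":
            out = out[out["cellularity"].isin(ADEQUATE_GRADES)]
        elif part == "indeterminate":
            out = out[out["cytology_class"].isin(("TIR3", "TIR4"))]
        else:
            raise ParameterError(f"unknown subgroup spec {part!r}")
    return out


def subgroup_report(
    diagnoses: pd.DataFrame,
    manifest: pd.DataFrame,
    subgroup: str,
    call_column: str = "call_pixel",
    level: float = 0.95,
) -> Optional[PerformanceReport]:
    """Performance report on a manifest subgroup for one aggregation rule.

    Samples with inadequate calls are dropped (with a warning).  Returns
    ``None`` for an empty subgroup.
    """
    df = diagnoses.merge(manifest, on="sample_id", suffixes=("", "_manifest"))
    df = filter_subgroup(df, subgroup)
    if len(df) == 0:
        warnings.warn(f"subgroup {subgroup!r} is empty", stacklevel=2)
        return None
    ok = df[call_column].isin(("benign", "malignant"))
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} sample(s) with unresolved calls",
            stacklevel=2,
        )
        df = df[ok]
        if len(df) == 0:
            return None
    counts = confusion(list(df[call_column]), list(df["truth_label"]))
    return diagnostic_metrics(counts, level=level, subgroup=subgroup)


#: Display order of histology subtypes in the three-level cross-tab.
_SUBTYPE_ORDER = ("HP", "HT", "FA", "NIFTP", "WDT-UMP", "PTC", "MTC", "other")
_BANDS = ("benign", "gray", "malignant")


def three_level_table(diagnoses: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate truth subtype x three-level call.

    Rows are subtypes (with their truth label as a second index level);
    columns are the benign/gray/malignant calls.  Row sums equal subtype
    totals.
    """
    df = diagnoses.merge(manifest, on="sample_id", suffixes=("", "_manifest"))
    if "call_three_level" not in df.columns:
        raise ParameterError("diagnoses frame lacks a call_three_level column")
    tab = pd.crosstab([df["truth_label"], df["subtype"]], df["call_three_level"])
    for band in _BANDS:
        if band not in tab.columns:
            tab[band] = 0
    tab = tab[list(_BANDS)]
    order = [
        (t, s)
        for t in ("benign", "malignant")
        for s in _SUBTYPE_ORDER
        if (t, s) in tab.index
    ]
    return tab.loc[order]


def three_level_agreement(
    table: pd.DataFrame, truth: str = "malignant", count_gray: bool = True
) -> float:
    """Fraction of ``truth`` samples whose triage call agrees with truth.

    With ``count_gray`` the gray-zone cases count as agreement (they are
    triaged to follow-up rather than miscalled).
    """
    if truth not in ("benign", "malignant"):
        raise ParameterError(f"unknown truth label {truth!r}")
    sub = table.loc[[i for i in table.index if i[0] == truth]]
    total = int(sub.to_numpy().sum())
    if total == 0:
        raise ParameterError(f"no {truth} samples in table")
    agree = int(sub[truth].sum())
    if count_gray:
        agree += int(sub["gray"].sum())
    return agree / total


# ---------------------------------------------------------------------------
# Exploratory PCA
# ---------------------------------------------------------------------------

def pca_explore(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of sample spectra on scaled and centered data.

    Columns are centered and scaled to unit variance (n-1 denominator);
    zero-variance columns are dropped with a warning.  Returns scores for
    every component with a positive eigenvalue and the explained-variance
    fractions (summing to 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, p = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 samples")
    if p < 2:
        raise ParameterError("PCA needs at least 2 features")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s) before PCA",
            stacklevel=2,
        )
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ParameterError("no non-constant features for PCA")
    Z = (X - X.mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    pos = eig > eig.max() * 1e-12
    scores = U[:, pos] * s[pos]
    evr = eig[pos] / eig[pos].sum()
    return scores, evr
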