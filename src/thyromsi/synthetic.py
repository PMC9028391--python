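"""Synthetic MALDI-MSI cohort generation.

No public dataset of thyroid FNA needle-wash MSI spectra exists, so this
module generates cohorts with the statistical structure the analysis
assumes: three spectral phenotypes (HP, HT, PTC) defined by Gaussian peak
templates on the 3000-15000 m/z acquisition range, per-pixel noise
(exponential baseline, truncated additive noise, height jitter, peak
dropout), benign/malignant pixel mixtures within a nodule, and cellularity
grades that control the fraction of informative (template-bearing) pixels
versus background-only pixels.

The default cohort design mirrors a two-stage clinical study: a training set
of 70 adequate-cellularity nodules (40 HP + 10 HT benign, 20 PTC malignant)
and a validation set of 170 nodules split 33/77/19/41 across the TIR2-TIR5
cytology tiers, including borderline histologies (FA, NIFTP, WDT-UMP) and a
mix of cellularity grades.

Randomness is hierarchical: each nodule draws from its own stream derived
from (cohort seed, nodule index), so appending nodules to a design never
perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from thyromsi.errors import ParameterError
from thyromsi.model import (
    CLASS_LABELS,
    CohortManifest,
    ManifestRecord,
    MZ_RANGE,
    NoduleSample,
    PixelSpectrum,
    RoiAnnotation,
    default_mz_grid,
)

#: Informative-pixel fraction bands implied by the semi-quantitative
#: cellularity grading (fraction of thyrocyte-bearing pixels).
CELLULARITY_BANDS = {
    "poor": (0.20, 0.30),
    "good": (0.30, 0.70),
    "optimal": (0.70, 1.00),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassTemplate:
    """Peak template of one spectral phenotype.

    Peaks are Gaussians in m/z; widths grow linearly with m/z, emulating
    linear-mode MALDI broadening (sigma = 2 Da at m/z 5000 by default).
    """

    class_label: str
    peak_mzs: np.ndarray
    peak_heights: np.ndarray
    peak_widths: np.ndarray
    shared_peak_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("peak_mzs", "peak_heights", "peak_widths"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.class_label not in CLASS_LABELS:
            raise ParameterError(f"unknown class label {self.class_label!r}")
        if self.peak_mzs.size == 0:
            raise ParameterError("template needs at least one peak")
        if np.any(np.diff(self.peak_mzs) <= 0):
            raise ParameterError("peak_mzs must be strictly increasing")
        if self.peak_mzs[0] < MZ_RANGE[0] or self.peak_mzs[-1] > MZ_RANGE[1]:
            raise ParameterError("peak positions outside the acquisition range")
        if np.any(self.peak_heights <= 0) or np.any(self.peak_widths <= 0):
            raise ParameterError("peak heights and widths must be strictly positive")
        if not 0.0 <= self.shared_peak_fraction <= 1.0:
            raise ParameterError("shared_peak_fraction must lie in [0, 1]")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_mzs.size)

    def signal_on_grid(self, mz_grid: np.ndarray) -> np.ndarray:
        """Noiseless spectrum: sum of the template Gaussians on the grid."""
        return _gaussian_mixture(mz_grid, self.peak_mzs, self.peak_heights, self.peak_widths)


@dataclass(frozen=True)
class NoiseModel:
    """Per-pixel degradation model.

    baseline_amplitude/decay: exponential chemical baseline (intensity, 1/Da);
    additive_noise_sd: detector noise, truncated at zero (half-normal, mean
    sd/sqrt(2*pi)); intensity_jitter_cv: multiplicative height jitter;
    dropout_prob: probability a template peak is absent in a given pixel.

    Defaults put single-pixel peaks at a raw signal-to-noise of roughly
    3-6 on full-content samples, so that adequate-cellularity pixels
    classify almost perfectly (benign pixels ~2% misclassified) while the
    attenuated spectra of sparsely cellular samples genuinely lose peaks --
    the regime a linear-mode protein profile of a clinical needle wash
    lives in.
    """

    baseline_amplitude: float = 25.0
    baseline_decay: float = 5e-4
    additive_noise_sd: float = 16.0
    intensity_jitter_cv: float = 0.3
    dropout_prob: float = 0.15

    def __post_init__(self) -> None:
        if min(self.baseline_amplitude, self.baseline_decay, self.additive_noise_sd) < 0:
            raise ParameterError("noise parameters must be nonnegative")
        if not 0.0 <= self.intensity_jitter_cv < 1.0:
            raise ParameterError("intensity_jitter_cv must lie in [0, 1)")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ParameterError("dropout_prob must lie in [0, 1]")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Design of one synthetic cohort (training + validation).

    ``cellularity_grade=None`` reproduces the study design: adequate
    (good/optimal) training samples and a validation set with a fixed mix of
    poor/good/optimal grades.  Setting a concrete grade forces it on every
    validation sample (training stays adequate), which is how quality
    degradation is studied.
    """

    n_hp_train: int = 40
    n_ht_train: int = 10
    n_ptc_train: int = 20
    validation_counts: Mapping[str, int] = field(
        default_factory=lambda: {"TIR2": 33, "TIR3": 77, "TIR4": 19, "TIR5": 41}
    )
    pixels_per_nodule: int = 1000
    rois_per_nodule: int = 8
    roi_pixel_fraction: float = 0.5
    malignant_pixel_fraction: float = 0.9
    borderline_malignant_fraction: float = 0.10
    cellularity_grade: Optional[str] = None
    n_peaks_per_class: int = 10
    shared_peak_fraction: float = 0.3
    mz_step: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hp_train", "n_ht_train", "n_ptc_train", "pixels_per_nodule", "rois_per_nodule"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("roi_pixel_fraction", "malignant_pixel_fraction", "borderline_malignant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.cellularity_grade is not None and self.cellularity_grade not in CELLULARITY_BANDS:
            raise ParameterError(f"unknown cellularity grade {self.cellularity_grade!r}")
        if any(c < 0 for c in self.validation_counts.values()):
            raise ParameterError("validation counts must be nonnegative")

    def mz_grid(self) -> np.ndarray:
        return default_mz_grid(self.mz_step)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_class_templates(
    rng_seed: int,
    n_peaks_per_class: int = 10,
    shared_peak_fraction: float = 0.3,
    ensure_unique: bool = True,
) -> dict[str, ClassTemplate]:
    """Build the HP/HT/PTC peak templates.

    A ``shared_peak_fraction`` of each template's peaks is common to all
    three classes; on top of that the two benign classes (HP, HT) share an
    extra block of peaks with each other, so HP and HT are spectrally closer
    to one another than either is to PTC.  With ``ensure_unique`` every class
    keeps at least one peak found in no other class (separability guarantee).
    ``shared_peak_fraction=0`` yields pairwise-disjoint peak sets.
    """
    if n_peaks_per_class < 2:
        raise ParameterError("n_peaks_per_class must be >= 2")
    if not 0.0 <= shared_peak_fraction < 1.0:
        raise ParameterError("shared_peak_fraction must lie in [0, 1)")

    n = n_peaks_per_class
    n_shared = int(round(shared_peak_fraction * n))
    if ensure_unique:
        n_shared = min(n_shared, n - 1)
    # benign-only extra sharing between HP and HT
    n_benign = 0
    if shared_peak_fraction > 0:
        n_benign = max(1, int(round(shared_peak_fraction * (n - n_shared) / 2)))
        if ensure_unique:
            n_benign = min(n_benign, n - n_shared - 1)
        n_benign = max(n_benign, 0)

    n_uniq_hp = n - n_shared - n_benign
    n_uniq_ht = n - n_shared - n_benign
    n_uniq_ptc = n - n_shared
    total = n_shared + n_benign + n_uniq_hp + n_uniq_ht + n_uniq_ptc

    rng = np.random.default_rng(rng_seed)
    # distinct positions with a minimum gap so peaks never collide in binning
    lattice = np.arange(MZ_RANGE[0] + 100.0, MZ_RANGE[1] - 100.0, 30.0)
    if total > lattice.size:
        raise ParameterError("too many peaks requested for the acquisition range")
    positions = rng.choice(lattice, size=total, replace=False)
    positions += rng.uniform(-5.0, 5.0, size=total)
    roles = rng.permutation(total)

    idx = 0

    def take(k: int) -> np.ndarray:
        nonlocal idx
        out = positions[roles[idx: idx + k]]
        idx += k
        return out

    shared = take(n_shared)
    benign = take(n_benign)
    uniq = {"HP": take(n_uniq_hp), "HT": take(n_uniq_ht), "PTC": take(n_uniq_ptc)}

    templates = {}
    for label in CLASS_LABELS:
        mzs = np.concatenate([shared, benign if label in ("HP", "HT") else np.empty(0), uniq[label]])
        order = np.argsort(mzs)
        mzs = mzs[order]
        heights = rng.uniform(40.0, 100.0, size=mzs.size)
        widths = 2.0 * mzs / 5000.0
        templates[label] = ClassTemplate(
            class_label=label,
            peak_mzs=mzs,
            peak_heights=heights,
            peak_widths=widths,
            shared_peak_fraction=shared_peak_fraction,
        )
    return templates


def _gaussian_mixture(
    grid: np.ndarray,
    mzs: np.ndarray,
    heights: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    """Sum of Gaussians, each evaluated only on its +/- 6 sigma window."""
    if grid.size == 0:
        raise ParameterError("empty m/z grid")
    out = np.zeros_like(grid, dtype=np.float64)
    for mu, h, sig in zip(mzs, heights, widths):
        lo = np.searchsorted(grid, mu - 6.0 * sig)
        hi = np.searchsorted(grid, mu + 6.0 * sig)
        if hi > lo:
            seg = grid[lo:hi]
            out[lo:hi] += h * np.exp(-0.5 * ((seg - mu) / sig) ** 2)
    return out


# ---------------------------------------------------------------------------
# Pixels
# ---------------------------------------------------------------------------

def simulate_pixel(
    template: Optional[ClassTemplate],
    noise: NoiseModel,
    mz_grid: np.ndarray,
    rng: np.random.Generator,
    x: int = 1,
    y: int = 1,
) -> PixelSpectrum:
    """Simulate one pixel spectrum.

    intensity = surviving template Gaussians + exponential baseline +
    truncated-at-zero additive noise.  ``template=None`` yields a
    background-only pixel (baseline + noise).  All intensities are >= 0.
    """
    mz_grid = np.asarray(mz_grid, dtype=np.float64)
    if mz_grid.size == 0:
        raise ParameterError("empty m/z grid")
    intensity = _pixel_intensity(template, noise, mz_grid, rng)
    return PixelSpectrum(x=x, y=y, mz=mz_grid, intensity=intensity)


def _pixel_intensity(
    template: Optional[ClassTemplate],
    noise: NoiseModel,
    mz_grid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.zeros_like(mz_grid)
    if template is not None:
        keep = np.ones(template.n_peaks, dtype=bool)
        if noise.dropout_prob > 0:
            keep = rng.random(template.n_peaks) >= noise.dropout_prob
        heights = template.peak_heights.copy()
        if noise.intensity_jitter_cv > 0:
            jitter = 1.0 + noise.intensity_jitter_cv * rng.standard_normal(template.n_peaks)
            heights = heights * np.clip(jitter, 0.0, None)
        if keep.any():
            out += _gaussian_mixture(
                mz_grid,
                template.peak_mzs[keep],
                heights[keep],
                template.peak_widths[keep],
            )
    if noise.baseline_amplitude > 0:
        out += noise.baseline_amplitude * np.exp(
            -noise.baseline_decay * (mz_grid - mz_grid[0])
        )
    if noise.additive_noise_sd > 0:
        out += np.clip(
            rng.normal(0.0, noise.additive_noise_sd, size=mz_grid.size), 0.0, None
        )
    return out


# ---------------------------------------------------------------------------
# Nodules
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fracs: Sequence[float], total: int) -> list[int]:
    raw = [f * total for f in fracs]
    counts = [int(math.floor(r)) for r in raw]
    short = total - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(short):
        counts[order[i]] += 1
    return counts


def simulate_nodule(
    truth_label: str,
    composition: Mapping[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
    templates: Optional[Mapping[str, ClassTemplate]] = None,
    sample_id: str = "S1",
    cytology_class: str = "unknown",
    subtype: str = "other",
    cellularity: str = "optimal",
) -> NoduleSample:
    """Simulate one nodule on a rectangular raster.

    The cellularity grade sets the fraction of informative pixels (drawn
    uniformly in its band); informative pixels are split across phenotypes
    per ``composition`` (fractions summing to 1) in contiguous row-major
    runs, and the remainder are background-only.  ROIs are axis-aligned,
    single-class rectangles covering about ``config.roi_pixel_fraction`` of
    each class's pixels.
    """
    comp = dict(composition)
    ssum = sum(comp.values())
    if abs(ssum - 1.0) > 1e-9:
        raise ParameterError(f"composition fractions must sum to 1 (got {ssum})")
    unknown = [c for c in comp if c not in CLASS_LABELS]
    if unknown:
        raise ParameterError(f"unknown class in composition: {unknown[0]!r}")
    if cellularity not in CELLULARITY_BANDS:
        raise ParameterError(f"unknown cellularity grade {cellularity!r}")
    if templates is None:
        templates = make_class_templates(
            config.rng_seed, config.n_peaks_per_class, config.shared_peak_fraction
        )

    n = config.pixels_per_nodule
    if n < 1:
        raise ParameterError("pixels_per_nodule must be >= 1")
    ncols = int(math.ceil(math.sqrt(n)))
    coords = [(i % ncols + 1, i // ncols + 1) for i in range(n)]

    lo, hi = CELLULARITY_BANDS[cellularity]
    informative_frac = rng.uniform(lo, hi)
    n_inform = int(round(informative_frac * n))

    # Signal amplitude scales with cellular content: sparsely cellular
    # samples yield low-signal spectra even on their informative pixels,
    # while instrument noise and baseline stay fixed.
    scaled = {
        lab: replace(t, peak_heights=t.peak_heights * informative_frac)
        for lab, t in templates.items()
    }

    present = [c for c in CLASS_LABELS if comp.get(c, 0.0) > 0]
    counts = _largest_remainder_counts([comp[c] for c in present], n_inform)

    mz_grid = config.mz_grid()
    pixel_classes: dict = {}
    pixels: list[PixelSpectrum] = []
    runs: dict[str, tuple[int, int]] = {}
    pos = 0
    for label, cnt in zip(present, counts):
        runs[label] = (pos, pos + cnt)
        for i in range(pos, pos + cnt):
            x, y = coords[i]
            pixels.append(simulate_pixel(scaled[label], config.noise, mz_grid, rng, x=x, y=y))
            pixel_classes[(x, y)] = label
        pos += cnt
    for i in range(pos, n):
        x, y = coords[i]
        pixels.append(simulate_pixel(None, config.noise, mz_grid, rng, x=x, y=y))
        pixel_classes[(x, y)] = None

    rois = _carve_rois(sample_id, runs, coords, ncols, config)
    return NoduleSample(
        sample_id=sample_id,
        cytology_class=cytology_class,
        truth_label=truth_label,
        subtype=subtype,
        cellularity=cellularity,
        pixels=pixels,
        rois=rois,
        pixel_classes=pixel_classes,
    )


def _carve_rois(
    sample_id: str,
    runs: Mapping[str, tuple[int, int]],
    coords: Sequence[tuple[int, int]],
    ncols: int,
    config: CohortConfig,
) -> list[RoiAnnotation]:
    """Carve axis-aligned rectangular single-class ROIs from the class runs.

    ROIs are built from complete raster rows inside a class's contiguous run
    (falling back to a height-1 segment when the run holds no complete row),
    targeting ``roi_pixel_fraction`` of each class's pixels; the per-nodule
    ROI budget is split across classes proportionally to their pixel counts.
    """
    total_inform = sum(b - a for a, b in runs.values())
    if total_inform == 0 or config.rois_per_nodule == 0:
        return []
    budget = max(config.rois_per_nodule, len(runs))
    alloc = {
        lab: max(1, int(round(budget * (b - a) / total_inform)))
        for lab, (a, b) in runs.items()
        if b > a
    }
    rois: list[RoiAnnotation] = []
    k = 0
    for lab, (a, b) in runs.items():
        if b <= a:
            continue
        n_rois = alloc[lab]
        target_px = max(1, int(round(config.roi_pixel_fraction * (b - a))))
        r_start = (a + ncols - 1) // ncols  # first complete row
        r_end = b // ncols                  # one past last complete row
        if r_end > r_start:
            rows_avail = r_end - r_start
            rows_use = min(rows_avail, max(n_rois, int(round(target_px / ncols))))
            n_rois = min(n_rois, rows_use)
            edges = np.linspace(r_start, r_start + rows_use, n_rois + 1).astype(int)
            for j in range(n_rois):
                r0, r1 = edges[j], edges[j + 1]
                if r1 <= r0:
                    continue
                pix = frozenset(coords[i] for i in range(r0 * ncols, r1 * ncols))
                rois.append(RoiAnnotation(f"{sample_id}-roi{k}", sample_id, lab, pix))
                k += 1
        else:
            # run confined within (at most two) partial rows: one short ROI
            seg_end = min(b, ((a // ncols) + 1) * ncols, a + target_px)
            seg_end = max(seg_end, a + 1)
            pix = frozenset(coords[i] for i in range(a, seg_end))
            rois.append(RoiAnnotation(f"{sample_id}-roi{k}", sample_id, lab, pix))
            k += 1
    return rois


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _composition_for(subtype: str, truth: str, config: CohortConfig) -> dict[str, float]:
    m = config.malignant_pixel_fraction
    b = config.borderline_malignant_fraction
    if truth == "malignant":  # PTC, MTC: dominant malignant phenotype
        return {"HP": 1.0 - m, "PTC": m} if m < 1.0 else {"PTC": 1.0}
    if subtype == "HT":
        return {"HT": 1.0}
    if subtype in ("FA", "NIFTP", "WDT-UMP"):
        # borderline histologies share spectral profiles with both groups
        return {"HP": 1.0 - b, "PTC": b} if b > 0 else {"HP": 1.0}
    return {"HP": 1.0}


def training_design(config: CohortConfig) -> list[ManifestRecord]:
    """Training-set design: adequate-cellularity benign (HP, HT) and PTC."""
    recs = []
    specs = (
        [("HP", "benign", "TIR2", config.n_hp_train)]
        + [("HT", "benign", "TIR2", config.n_ht_train)]
        + [("PTC", "malignant", "TIR5", config.n_ptc_train)]
    )
    i = 0
    for subtype, truth, tier, count in specs:
        for j in range(count):
            cell = "optimal" if i % 2 == 0 else "good"
            recs.append(
                ManifestRecord(
                    sample_id=f"TR{i:03d}",
                    cytology_class=tier,
                    truth_label=truth,
                    subtype=subtype,
                    cellularity=cell,
                    dataset="training",
                )
            )
            i += 1
    return recs


#: Per-tier validation composition: (subtype, truth, count, n_adequate).
#: Mirrors the study's margins: 170 cases (33/77/19/41 across TIR2-TIR5),
#: 105 benign / 65 malignant, 29 borderline histologies, and an
#: adequate-cellularity subset of 72 split 17/23/9/23 across tiers.
_VALIDATION_BLOCKS = {
    "TIR2": [("HP", "benign", 30, 16), ("HT", "benign", 3, 1)],
    "TIR3": [
        ("HP", "benign", 39, 15),
        ("FA", "benign", 22, 4),
        ("NIFTP", "benign", 5, 1),
        ("WDT-UMP", "benign", 2, 1),
        ("PTC", "malignant", 9, 2),
    ],
    "TIR4": [("PTC", "malignant", 15, 9), ("HP", "benign", 4, 0)],
    "TIR5": [("PTC", "malignant", 38, 21), ("MTC", "malignant", 3, 2)],
}


def validation_design(config: CohortConfig) -> list[ManifestRecord]:
    """Validation-set design with the default tier/truth/cellularity mix.

    When ``config.cellularity_grade`` is set, every sample receives that
    grade instead of the default mix.  Tier counts other than the default
    170-case design scale each block proportionally (largest remainder).
    """
    recs = []
    i = 0
    for tier in ("TIR2", "TIR3", "TIR4", "TIR5"):
        want = int(config.validation_counts.get(tier, 0))
        blocks = _VALIDATION_BLOCKS[tier]
        default_total = sum(b[2] for b in blocks)
        if want == default_total:
            counts = [b[2] for b in blocks]
        else:
            counts = _largest_remainder_counts(
                [b[2] / default_total for b in blocks], want
            )
        for (subtype, truth, default_count, n_adeq), count in zip(blocks, counts):
            if default_count > 0:
                n_adeq = int(round(n_adeq * count / default_count))
            for j in range(count):
                if config.cellularity_grade is not None:
                    cell = config.cellularity_grade
                elif j < n_adeq:
                    cell = "optimal" if j % 2 == 0 else "good"
                else:
                    cell = "poor"
                recs.append(
                    ManifestRecord(
                        sample_id=f"VA{i:03d}",
                        cytology_class=tier,
                        truth_label=truth,
                        subtype=subtype,
                        cellularity=cell,
                        dataset="validation",
                    )
                )
                i += 1
    return recs


def cohort_design(config: CohortConfig) -> CohortManifest:
    return CohortManifest(training_design(config) + validation_design(config))


def iter_cohort(
    config: CohortConfig,
    templates: Optional[Mapping[str, ClassTemplate]] = None,
    subset: str = "all",
) -> Iterator[NoduleSample]:
    """Yield the cohort's nodules one by one (training first).

    Each nodule uses an independent RNG stream keyed on (seed, design
    index), so the cohort is reproducible, samples can be re-simulated in
    isolation, and restricting to a ``subset`` ("training"/"validation")
    yields exactly the same nodules as the full sweep.
    """
    if subset not in ("all", "training", "validation"):
        raise ParameterError(f"unknown subset {subset!r}")
    if templates is None:
        templates = make_class_templates(
            config.rng_seed, config.n_peaks_per_class, config.shared_peak_fraction
        )
    for idx, rec in enumerate(cohort_design(config)):
        if subset != "all" and rec.dataset != subset:
            continue
        rng = np.random.default_rng([config.rng_seed, idx])
        comp = _composition_for(rec.subtype, rec.truth_label, config)
        yield simulate_nodule(
            rec.truth_label,
            comp,
            config,
            rng,
            templates=templates,
            sample_id=rec.sample_id,
            cytology_class=rec.cytology_class,
            subtype=rec.subtype,
            cellularity=rec.cellularity,
        )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[NoduleSample], list[NoduleSample], CohortManifest]:
    """Materialise the full cohort: (training set, validation set, manifest).

    For large designs prefer :func:`iter_cohort`, which streams nodules
    without holding every spectrum in memory.
    """
    manifest = cohort_design(config)
    train: list[NoduleSample] = []
    val: list[NoduleSample] = []
    by_id = {r.sample_id: r for r in manifest}
    for sample in iter_cohort(config):
        if by_id[sample.sample_id].dataset == "training":
            train.append(sample)
        else:
            val.append(sample)
    return train, val, manifest
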