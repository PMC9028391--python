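"""Spectral preprocessing and peak-feature extraction.

Raw pixel spectra pass through a fixed chain -- trim to the acquisition
range, Savitzky-Golay smoothing, SNIP baseline subtraction (clamped at
zero), TIC normalization -- before peak picking (local maxima above an
MAD-based signal-to-noise threshold) and m/z binning into a shared feature
axis.  The three analysis units are rows of one of three matrices: single
pixels, ROI-average spectra, and per-nodule overall-average spectra.  The
feature bins are learned once, from training ROI-average peaks, and frozen
for every other unit so validation never leaks into the feature axis.

Defaults mirror common MALDIquant-style practice: half-window 10, SNIP 100
iterations, TIC normalization, SNR 3, relative bin tolerance 0.002.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from thyromsi.errors import NoFeaturesError, ParameterError
from thyromsi.model import MZ_RANGE, NoduleSample, PixelSpectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    smoothing_half_window: int = 10
    baseline_iterations: int = 100
    normalization: str = "TIC"  # TIC | none
    peak_snr_threshold: float = 3.0
    bin_tolerance: float = 0.002  # relative m/z tolerance
    mz_range: tuple = MZ_RANGE

    def __post_init__(self) -> None:
        if self.smoothing_half_window < 1:
            raise ParameterError("smoothing_half_window must be >= 1")
        if self.baseline_iterations < 0:
            raise ParameterError("baseline_iterations must be >= 0")
        if self.normalization not in ("TIC", "none"):
            raise ParameterError(f"unknown normalization {self.normalization!r}")
        if self.peak_snr_threshold <= 0:
            raise ParameterError("peak_snr_threshold must be positive")
        if not 0.0 < self.bin_tolerance < 0.1:
            raise ParameterError("bin_tolerance must lie in (0, 0.1)")


# ---------------------------------------------------------------------------
# Spectrum-level chain
# ---------------------------------------------------------------------------

def snip_baseline(Y: np.ndarray, iterations: int) -> np.ndarray:
    """SNIP baseline estimate for each row of ``Y`` (spectra x points).

    Statistics-sensitive non-linear iterative peak clipping with an
    increasing window: at step m each point is replaced by the minimum of
    itself and the mean of its two m-distant neighbours (Jacobi update).
    """
    Y = np.asarray(Y)
    if Y.ndim == 1:
        return snip_baseline(Y[None, :], iterations)[0]
    # single-precision clipping: the baseline estimate is subtracted and
    # clamped, so ~1e-7 relative error is inconsequential
    B = np.array(Y, dtype=np.float32)
    n = B.shape[1]
    buf = np.empty_like(B)
    for m in range(1, iterations + 1):
        if 2 * m >= n:
            break
        mid = buf[:, m: n - m]
        np.add(B[:, : n - 2 * m], B[:, 2 * m:], out=mid)
        mid *= 0.5
        np.minimum(B[:, m: n - m], mid, out=B[:, m: n - m])
    return B.astype(np.float64)


def preprocess_matrix(
    mz: np.ndarray,
    Y: np.ndarray,
    cfg: PreprocessConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised preprocessing of a (pixels x points) intensity matrix.

    Returns (trimmed m/z axis, processed matrix, retained-row mask).  Rows
    that are empty after trimming or have zero TIC are flagged out (their
    processed values are zeros) and counted in the log.
    """
    mz = np.asarray(mz, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    lo, hi = cfg.mz_range
    sel = (mz >= lo) & (mz <= hi)
    mz_t = mz[sel]
    Y = Y[:, sel]
    if mz_t.size == 0:
        logger.info("all %d spectra empty after m/z trimming", Y.shape[0])
        return mz_t, np.zeros((Y.shape[0], 0)), np.zeros(Y.shape[0], dtype=bool)

    window = 2 * cfg.smoothing_half_window + 1
    if window > mz_t.size:
        window = mz_t.size if mz_t.size % 2 == 1 else mz_t.size - 1
    if window >= 5:
        Y = savgol_filter(Y, window_length=window, polyorder=3, axis=1)
        np.clip(Y, 0.0, None, out=Y)
    if cfg.baseline_iterations > 0:
        Y = Y - snip_baseline(Y, cfg.baseline_iterations)
        np.clip(Y, 0.0, None, out=Y)

    tic = Y.sum(axis=1)
    retained = tic > 0
    n_dropped = int((~retained).sum())
    if n_dropped:
        logger.info("excluded %d spectra with zero TIC after preprocessing", n_dropped)
    if cfg.normalization == "TIC":
        Y = np.where(retained[:, None], Y / np.where(tic == 0, 1.0, tic)[:, None], 0.0)
    return mz_t, Y, retained


def preprocess_spectrum(
    spec: PixelSpectrum, cfg: PreprocessConfig
) -> Optional[PixelSpectrum]:
    """Preprocess a single pixel spectrum.

    Returns ``None`` for spectra that are empty after trimming or have zero
    total ion current -- such pixels are excluded downstream and counted.
    """
    mz_t, Y, retained = preprocess_matrix(spec.mz, spec.intensity[None, :], cfg)
    if mz_t.size == 0 or not retained[0]:
        return None
    return PixelSpectrum(x=spec.x, y=spec.y, mz=mz_t, intensity=Y[0])


def average_spectrum(pixels: Sequence[PixelSpectrum]) -> PixelSpectrum:
    """Pointwise arithmetic mean of spectra sharing a common grid."""
    if not pixels:
        raise ParameterError("cannot average an empty set of spectra")
    mz = pixels[0].mz
    for p in pixels[1:]:
        if p.mz.shape != mz.shape or not np.array_equal(p.mz, mz):
            raise ParameterError("spectra are not on a common m/z grid")
    mean = np.mean([p.intensity for p in pixels], axis=0)
    return PixelSpectrum(x=1, y=1, mz=mz, intensity=mean)


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

def _mad_noise(Y: np.ndarray) -> np.ndarray:
    med = np.median(Y, axis=1, keepdims=True)
    return 1.4826 * np.median(np.abs(Y - med), axis=1)


def peak_mask_matrix(Y: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Boolean mask of peak apexes for each row of ``Y``.

    A peak is a positive local maximum (plateaus keep their left edge)
    whose robust z-score -- deviation from the row median over the
    1.4826*MAD noise scale -- reaches ``peak_snr_threshold``.  A zero noise
    scale (noiseless spectra) admits every positive local maximum.
    """
    Y = np.atleast_2d(Y)
    n = Y.shape[1]
    mask = np.zeros_like(Y, dtype=bool)
    if n < 3 or not np.isfinite(cfg.peak_snr_threshold):
        return mask
    core = (Y[:, 1:-1] >= Y[:, :-2]) & (Y[:, 1:-1] > Y[:, 2:])
    med = np.median(Y, axis=1, keepdims=True)
    noise = _mad_noise(Y)[:, None]
    dev = Y[:, 1:-1] - med
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, dev / np.where(noise > 0, noise, 1.0), np.inf)
    mask[:, 1:-1] = core & (Y[:, 1:-1] > 0) & (dev > 0) & (snr >= cfg.peak_snr_threshold)
    return mask


def pick_peaks(
    spec: PixelSpectrum, cfg: PreprocessConfig
) -> list[tuple[float, float]]:
    """Peak list [(m/z, intensity), ...] of a preprocessed spectrum."""
    mask = peak_mask_matrix(spec.intensity[None, :], cfg)[0]
    idx = np.flatnonzero(mask)
    return [(float(spec.mz[i]), float(spec.intensity[i])) for i in idx]


# ---------------------------------------------------------------------------
# Binning and feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Units x binned-m/z-features intensity matrix."""

    unit_ids: list
    feature_mzs: np.ndarray
    values: np.ndarray
    unit_level: str  # pixel | roi | overall

    def __post_init__(self) -> None:
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(self.unit_ids), self.feature_mzs.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} units x {self.feature_mzs.size} features"
            )
        if self.feature_mzs.size > 1 and np.any(np.diff(self.feature_mzs) <= 0):
            raise ParameterError("feature_mzs must be strictly increasing")
        if np.any(self.values < 0):
            raise ParameterError("feature values must be nonnegative")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, index=self.unit_ids, columns=self.feature_mzs)
        df.index.name = "unit_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str, unit_level: str = "roi") -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(
            unit_ids=list(df.index),
            feature_mzs=np.array([float(c) for c in df.columns]),
            values=df.to_numpy(),
            unit_level=unit_level,
        )


@dataclass(frozen=True)
class PeakBins:
    """Frozen m/z feature bins learned from training peaks.

    Each bin is the single-linkage cluster of training peaks obtained by
    sorting all peaks by m/z and splitting where the gap between neighbours
    exceeds the relative tolerance; the representative m/z is the
    intensity-weighted mean.  Peaks from any other unit are assigned to a
    bin when they fall inside its span widened by the tolerance.
    """

    feature_mzs: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    tolerance: float

    def assign(self, peaks) -> np.ndarray:
        """Sum peak intensities into the frozen bins (0 where absent).

        ``peaks`` is a sequence of (m/z, intensity) pairs or an equivalent
        (k, 2) array.
        """
        out = np.zeros(self.feature_mzs.size)
        arr = _as_peak_array(peaks)
        if arr.size == 0:
            return out
        mzs, ints = arr[:, 0], arr[:, 1]
        lo = self.lo * (1.0 - self.tolerance)
        hi = self.hi * (1.0 + self.tolerance)
        j = np.searchsorted(hi, mzs)
        ok = j < self.feature_mzs.size
        jj = np.where(ok, j, 0)
        ok &= (mzs >= lo[jj]) & (mzs <= hi[jj])
        np.add.at(out, jj[ok], ints[ok])
        return out


def _as_peak_array(peaks) -> np.ndarray:
    """(k, 2) float array view of a peak list."""
    arr = np.asarray(peaks, dtype=np.float64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("peaks must be (m/z, intensity) pairs")
    return arr


def learn_bins(
    peak_lists: Sequence[Sequence[tuple[float, float]]],
    tolerance: float,
) -> PeakBins:
    """Cluster peaks across units into m/z bins (order-independent)."""
    arrays = [a for a in (_as_peak_array(lst) for lst in peak_lists) if a.size]
    if not arrays:
        raise NoFeaturesError("no features: every peak list is empty")
    arr = np.vstack(arrays)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]  # by mz then intensity
    mzs, ints = arr[:, 0], arr[:, 1]
    gaps = np.diff(mzs) > tolerance * mzs[:-1]
    starts = np.concatenate([[0], np.flatnonzero(gaps) + 1, [mzs.size]])
    centers, los, his = [], [], []
    for a, b in zip(starts[:-1], starts[1:]):
        w = ints[a:b]
        if w.sum() > 0:
            centers.append(float(np.average(mzs[a:b], weights=w)))
        else:
            centers.append(float(mzs[a:b].mean()))
        los.append(float(mzs[a]))
        his.append(float(mzs[b - 1]))
    return PeakBins(
        feature_mzs=np.array(centers),
        lo=np.array(los),
        hi=np.array(his),
        tolerance=tolerance,
    )


def apply_bins(
    bins: PeakBins,
    peak_lists: Sequence[Sequence[tuple[float, float]]],
    unit_ids: Sequence,
    unit_level: str,
) -> FeatureMatrix:
    values = np.vstack([bins.assign(lst) for lst in peak_lists]) if peak_lists else np.zeros((0, bins.feature_mzs.size))
    return FeatureMatrix(
        unit_ids=list(unit_ids),
        feature_mzs=bins.feature_mzs,
        values=values,
        unit_level=unit_level,
    )


def bin_peaks(
    peak_lists: Sequence[Sequence[tuple[float, float]]],
    tolerance: float,
    unit_ids: Optional[Sequence] = None,
    unit_level: str = "roi",
) -> FeatureMatrix:
    """Merge peaks within relative tolerance into one feature per bin."""
    if unit_ids is None:
        unit_ids = list(range(len(peak_lists)))
    bins = learn_bins(peak_lists, tolerance)
    return apply_bins(bins, peak_lists, unit_ids, unit_level)


# ---------------------------------------------------------------------------
# Cohort-level matrices
# ---------------------------------------------------------------------------

@dataclass
class SampleFeatures:
    """Per-sample preprocessing product: peak lists for each analysis unit."""

    sample_id: str
    pixel_ids: list
    pixel_peaks: list
    roi_ids: list
    roi_labels: list
    roi_peaks: list
    overall_peaks: list
    n_pixels_retained: int
    n_pixels_dropped: int
    pixel_truth: Optional[list] = None


def extract_sample_features(sample: NoduleSample, cfg: PreprocessConfig) -> SampleFeatures:
    """Preprocess one nodule and reduce each unit to its peak list.

    Pixels with zero TIC after preprocessing are excluded (counted); the
    overall-average and ROI-average spectra are means of the retained
    preprocessed pixels (per-pixel TIC normalization equalises weights).
    """
    mz, Y = sample.intensity_matrix()
    mz_t, P, retained = preprocess_matrix(mz, Y, cfg)
    coords = [p.coord for p in sample.pixels]

    pixel_ids, pixel_peaks, pixel_truth = [], [], []
    mask = peak_mask_matrix(P, cfg) if mz_t.size else np.zeros_like(P, dtype=bool)
    for i, coord in enumerate(coords):
        if not retained[i]:
            continue
        idx = np.flatnonzero(mask[i])
        pixel_ids.append((sample.sample_id, coord))
        pixel_peaks.append(np.column_stack((mz_t[idx], P[i, idx])))
        if sample.pixel_classes is not None:
            pixel_truth.append(sample.pixel_classes.get(coord))

    coord_row = {c: i for i, c in enumerate(coords)}
    roi_ids, roi_labels, roi_peaks = [], [], []
    for roi in sample.rois:
        rows = [coord_row[c] for c in roi.pixels if c in coord_row]
        rows = [r for r in rows if retained[r]]
        if not rows:
            continue
        avg = P[rows].mean(axis=0)
        pk = peak_mask_matrix(avg[None, :], cfg)[0]
        idx = np.flatnonzero(pk)
        roi_ids.append(roi.roi_id)
        roi_labels.append(roi.label)
        roi_peaks.append(np.column_stack((mz_t[idx], avg[idx])))

    if retained.any():
        overall = P[retained].mean(axis=0)
        pk = peak_mask_matrix(overall[None, :], cfg)[0]
        idx = np.flatnonzero(pk)
        overall_peaks = np.column_stack((mz_t[idx], overall[idx]))
    else:
        overall_peaks = np.zeros((0, 2))

    return SampleFeatures(
        sample_id=sample.sample_id,
        pixel_ids=pixel_ids,
        pixel_peaks=pixel_peaks,
        roi_ids=roi_ids,
        roi_labels=roi_labels,
        roi_peaks=roi_peaks,
        overall_peaks=overall_peaks,
        n_pixels_retained=int(retained.sum()),
        n_pixels_dropped=int((~retained).sum()),
        pixel_truth=pixel_truth if sample.pixel_classes is not None else None,
    )


def build_unit_matrices(
    samples: Sequence[NoduleSample],
    cfg: PreprocessConfig,
    bins: Optional[PeakBins] = None,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, PeakBins, dict]:
    """Build the pixel/ROI/overall feature matrices on one shared axis.

    When ``bins`` is None the bins are learned from this cohort's ROI-average
    peaks (training usage) and returned for reuse on other cohorts.  Also
    returns per-ROI labels and counters in the metadata dict.
    """
    feats = [extract_sample_features(s, cfg) for s in samples]
    return assemble_matrices(feats, cfg, bins)


def assemble_matrices(
    feats: Sequence[SampleFeatures],
    cfg: PreprocessConfig,
    bins: Optional[PeakBins] = None,
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, PeakBins, dict]:
    if bins is None:
        roi_lists = [pk for f in feats for pk in f.roi_peaks]
        bins = learn_bins(roi_lists, cfg.bin_tolerance)
    pixel_fm = apply_bins(
        bins,
        [pk for f in feats for pk in f.pixel_peaks],
        [pid for f in feats for pid in f.pixel_ids],
        "pixel",
    )
    roi_fm = apply_bins(
        bins,
        [pk for f in feats for pk in f.roi_peaks],
        [rid for f in feats for rid in f.roi_ids],
        "roi",
    )
    overall_fm = apply_bins(
        bins,
        [f.overall_peaks for f in feats],
        [f.sample_id for f in feats],
        "overall",
    )
    meta = {
        "roi_labels": [lab for f in feats for lab in f.roi_labels],
        "n_pixels_dropped": sum(f.n_pixels_dropped for f in feats),
        "pixel_sample_ids": [pid[0] for f in feats for pid in f.pixel_ids],
    }
    return pixel_fm, roi_fm, overall_fm, bins, meta
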