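"""Core data model: pixel spectra, ROI annotations, nodule samples, manifests.

Coordinates follow the imzML convention and are 1-based.  A pixel is the
atomic spectral unit (one mass spectrum per 50 x 50 um raster position); an
ROI is a pathologist-style annotation grouping pixels of one cell population;
a nodule sample bundles the pixels and ROIs of one FNA needle wash together
with its cytology tier, cellularity grade and histology/follow-up truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from thyromsi.errors import FormatError, ParameterError, RoiValidationError

#: The three spectral phenotypes, in canonical model order.
CLASS_LABELS = ("HP", "HT", "PTC")
#: Phenotypes mapping to a benign per-nodule call.
BENIGN_CLASSES = frozenset({"HP", "HT"})
#: SIAPEC/Bethesda 5-tiered cytology classes used here (TIR2..TIR5).
CYTOLOGY_CLASSES = ("TIR2", "TIR3", "TIR4", "TIR5")
#: Semi-quantitative thyrocyte-content grades.
CELLULARITY_GRADES = ("poor", "good", "optimal")
#: Histology/follow-up subtypes recognised by the manifest.
SUBTYPES = ("HP", "HT", "PTC", "FA", "NIFTP", "WDT-UMP", "MTC", "other")
TRUTH_LABELS = ("benign", "malignant", "unknown")

#: Acquisition mass range (Da), linear positive mode.
MZ_RANGE = (3000.0, 15000.0)


def default_mz_grid(step: float = 1.0) -> np.ndarray:
    """Common m/z axis covering the acquisition range at ``step`` Da spacing."""
    if step <= 0:
        raise ParameterError(f"grid step must be positive, got {step}")
    return np.arange(MZ_RANGE[0], MZ_RANGE[1] + 0.5 * step, step, dtype=np.float64)


@dataclass
class PixelSpectrum:
    """One mass spectrum tied to an (x, y) raster position.

    ``mz`` must be strictly increasing and ``intensity`` nonnegative with
    matching length.
    """

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ParameterError(
                f"mz and intensity must be 1-D arrays of equal length "
                f"(got {self.mz.shape} vs {self.intensity.shape})"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise FormatError("m/z axis is not strictly increasing")
        if self.intensity.size and float(self.intensity.min()) < 0:
            raise ParameterError("intensities must be nonnegative")

    @property
    def coord(self) -> tuple[int, int]:
        return (self.x, self.y)

    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())


@dataclass(frozen=True)
class RoiAnnotation:
    """A labelled, nonempty set of pixel positions within one sample."""

    roi_id: str
    sample_id: str
    label: str  # HP | HT | PTC | unlabeled
    pixels: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", frozenset(tuple(p) for p in self.pixels))
        if not self.pixels:
            raise RoiValidationError(f"ROI {self.roi_id!r} has no pixels")
        if self.label not in CLASS_LABELS and self.label != "unlabeled":
            raise ParameterError(f"unknown ROI label {self.label!r}")

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class NoduleSample:
    """One FNA nodule: metadata plus its pixel spectra and ROI annotations.

    ``pixel_classes`` optionally records the generating phenotype of each
    pixel (synthetic cohorts only; ``None`` marks background/noise pixels).
    """

    sample_id: str
    cytology_class: str
    truth_label: str
    subtype: str
    cellularity: str
    pixels: list = field(default_factory=list)
    rois: list = field(default_factory=list)
    pixel_classes: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.cytology_class not in CYTOLOGY_CLASSES + ("unknown",):
            raise ParameterError(f"unknown cytology class {self.cytology_class!r}")
        if self.truth_label not in TRUTH_LABELS:
            raise ParameterError(f"unknown truth label {self.truth_label!r}")
        if self.cellularity not in CELLULARITY_GRADES + ("unknown",):
            raise ParameterError(f"unknown cellularity grade {self.cellularity!r}")
        self.validate_rois()

    def validate_rois(self) -> None:
        """Enforce that ROI pixels exist in the raster and do not overlap."""
        coords = {p.coord for p in self.pixels}
        seen: dict = {}
        for roi in self.rois:
            missing = roi.pixels - coords
            if missing:
                raise RoiValidationError(
                    f"ROI {roi.roi_id!r} references pixels outside sample "
                    f"{self.sample_id!r} raster: {sorted(missing)[:3]}"
                )
            for p in roi.pixels:
                if p in seen:
                    raise RoiValidationError(
                        f"ROIs {seen[p]!r} and {roi.roi_id!r} overlap at pixel {p}"
                    )
                seen[p] = roi.roi_id

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def raster_shape(self) -> tuple[int, int]:
        """(n_columns, n_rows) spanned by the pixel coordinates."""
        if not self.pixels:
            return (0, 0)
        xs = [p.x for p in self.pixels]
        ys = [p.y for p in self.pixels]
        return (max(xs), max(ys))

    def intensity_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack pixel spectra as (shared m/z axis, pixels x points matrix).

        Requires a common grid across pixels (continuous-mode data).
        """
        if not self.pixels:
            raise ParameterError(f"sample {self.sample_id!r} has no pixels")
        mz = self.pixels[0].mz
        for p in self.pixels[1:]:
            if p.mz.shape != mz.shape or not np.array_equal(p.mz, mz):
                raise ParameterError(
                    f"sample {self.sample_id!r} pixels are not on a common m/z grid"
                )
        return mz, np.vstack([p.intensity for p in self.pixels])


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    cytology_class: str
    truth_label: str
    subtype: str
    cellularity: str
    path: str = ""
    dataset: str = ""  # training | validation (optional bookkeeping)


class CohortManifest:
    """Ordered collection of per-sample metadata with unique sample ids."""

    REQUIRED_COLUMNS = ("sample_id", "cytology_class", "truth_label", "subtype", "cellularity")

    def __init__(self, records: Iterable[ManifestRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample ids in manifest: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ManifestRecord]:
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> ManifestRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortManifest":
        missing = [c for c in cls.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest is missing required columns: {missing}")
        recs = [
            ManifestRecord(
                sample_id=str(row.sample_id),
                cytology_class=str(row.cytology_class),
                truth_label=str(row.truth_label),
                subtype=str(row.subtype),
                cellularity=str(row.cellularity),
                path=str(getattr(row, "path", "") or ""),
                dataset=str(getattr(row, "dataset", "") or ""),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(recs)
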