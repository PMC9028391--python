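"""Reading and writing the standard formats the pipeline touches.

imzML 1.1 + ibd pairs carry the pixel spectra (continuous and processed
modes both supported; processed-mode spectra are resampled onto a common
grid by linear interpolation).  Manifests and ROI annotations are plain CSV.
Per-pixel class calls can be rendered to a PNG raster map using the
green/yellow/red convention (HP/HT/PTC).
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from thyromsi.errors import FormatError, ParameterError, RoiValidationError
from thyromsi.model import (
    CohortManifest,
    NoduleSample,
    PixelSpectrum,
    RoiAnnotation,
    default_mz_grid,
)

#: Raster colors for the per-pixel class maps (RGBA).
CLASS_COLORS = {
    "HP": (0, 160, 60, 255),     # green
    "HT": (235, 200, 30, 255),   # yellow
    "PTC": (215, 25, 25, 255),   # red
}
_BACKGROUND = (255, 255, 255, 0)  # transparent white

ROI_CSV_COLUMNS = ("sample_id", "roi_id", "label", "x", "y")


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def write_imzml(spectra: Sequence[PixelSpectrum], path: str, mode: str = "continuous") -> str:
    """Write pixel spectra to an imzML/ibd pair.

    m/z values are stored as float64 and intensities as float32, the common
    imzML practice.  Returns the imzML path.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if mode not in ("continuous", "processed"):
        raise ParameterError(f"unknown imzML mode {mode!r}")
    if len(spectra) == 0:
        return _write_empty_imzml(str(path), mode)
    with ImzMLWriter(
        path,
        mode=mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for spec in spectra:
            writer.addSpectrum(spec.mz, spec.intensity, coords=(spec.x, spec.y, 1))
    if not str(path).endswith(".imzML"):
        path = str(path) + ".imzML"
    return str(path)


_EMPTY_IMZML = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="IMS" fullName="Imaging MS Ontology" URI="https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="IMS" accession="IMS:1000030" name="{mode}" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{{{uuid}}}"/>
    </fileContent>
  </fileDescription>
  <referenceableParamGroupList count="0"/>
  <softwareList count="1">
    <software id="thyromsi" version="0"/>
  </softwareList>
  <scanSettingsList count="1">
    <scanSettings id="scansettings1">
      <cvParam cvRef="IMS" accession="IMS:1000042" name="max count of pixels x" value="0"/>
      <cvParam cvRef="IMS" accession="IMS:1000043" name="max count of pixels y" value="0"/>
    </scanSettings>
  </scanSettingsList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="1" softwareRef="thyromsi"/>
    </dataProcessing>
  </dataProcessingList>
  <run defaultInstrumentConfigurationRef="IC1" id="run1">
    <spectrumList count="0" defaultDataProcessingRef="export"/>
  </run>
</mzML>
"""


def _write_empty_imzml(path: str, mode: str) -> str:
    """A valid imzML/ibd pair holding zero spectra (pyimzml cannot emit one)."""
    import uuid as uuid_mod

    if not path.endswith(".imzML"):
        path = path + ".imzML"
    uid = uuid_mod.uuid4()
    with open(os.path.splitext(path)[0] + ".ibd", "wb") as fh:
        fh.write(uid.bytes)
    with open(path, "w") as fh:
        fh.write(_EMPTY_IMZML.format(mode=mode, uuid=str(uid)))
    return path


def _count_spectra_in_xml(path: str) -> int:
    from lxml import etree

    try:
        tree = etree.parse(path)
    except Exception as exc:
        raise FormatError(f"malformed imzML XML in {path}: {exc}") from exc
    return len(tree.findall(".//{http://psi.hupo.org/ms/mzml}spectrum"))


def read_imzml(
    path: str,
    mz_grid: Optional[np.ndarray] = None,
) -> tuple[list[PixelSpectrum], dict]:
    """Read an imzML/ibd pair into pixel spectra plus raster metadata.

    Continuous-mode files keep their native (shared) axis unless ``mz_grid``
    is given.  Processed-mode files, where each pixel may carry its own axis,
    are resampled by linear interpolation onto ``mz_grid`` (default: the
    1 Da acquisition grid).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    if not os.path.exists(path):
        raise FormatError(f"imzML file not found: {path}")
    ibd = os.path.splitext(str(path))[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FormatError(f"missing ibd companion for {path}")

    if _count_spectra_in_xml(str(path)) == 0:
        # pyimzml's parser cannot handle a spectrum-free file
        return [], {
            "n_spectra": 0,
            "mode": "continuous",
            "raster_shape": (0, 0),
            "mz_range": (None, None),
        }
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML, bad binary metadata, ...
        raise FormatError(f"cannot parse imzML file {path}: {exc}") from exc

    n = len(parser.coordinates)
    # Continuous files share one m/z array: every spectrum points at the same
    # ibd offset.
    offsets = getattr(parser, "mzOffsets", [])
    continuous = n > 0 and len(set(offsets)) <= 1

    spectra: list[PixelSpectrum] = []
    shared_mz: Optional[np.ndarray] = None
    for i in range(n):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise FormatError(f"spectrum {i} in {path} has an unsorted m/z axis")
        x, y = parser.coordinates[i][0], parser.coordinates[i][1]
        if mz_grid is not None and (mz.shape != mz_grid.shape or not np.allclose(mz, mz_grid)):
            inten = np.interp(mz_grid, mz, inten, left=0.0, right=0.0)
            mz = mz_grid
        elif not continuous and mz_grid is None:
            if shared_mz is None:
                shared_mz = default_mz_grid()
            inten = np.interp(shared_mz, mz, inten, left=0.0, right=0.0)
            mz = shared_mz
        elif continuous and shared_mz is None:
            shared_mz = mz
        elif continuous:
            mz = shared_mz  # share the array object across pixels
        spectra.append(PixelSpectrum(x=int(x), y=int(y), mz=mz, intensity=inten))

    meta = {
        "n_spectra": n,
        "mode": "continuous" if continuous else "processed",
        "raster_shape": (
            max((s.x for s in spectra), default=0),
            max((s.y for s in spectra), default=0),
        ),
        "mz_range": (
            float(spectra[0].mz[0]) if spectra else None,
            float(spectra[0].mz[-1]) if spectra else None,
        ),
    }
    return spectra, meta


def imzml_summary(path: str) -> str:
    """One-line human-readable summary used by the ``inspect`` CLI command."""
    spectra, meta = read_imzml(path)
    lo, hi = meta["mz_range"]
    rng = f"{lo:.1f}-{hi:.1f}" if lo is not None else "n/a"
    return (
        f"{os.path.basename(str(path))}: {meta['n_spectra']} spectra "
        f"({meta['mode']} mode), raster {meta['raster_shape'][0]}x{meta['raster_shape'][1]}, "
        f"m/z {rng}"
    )


# ---------------------------------------------------------------------------
# Manifest and ROI CSV
# ---------------------------------------------------------------------------

def write_manifest(manifest: CohortManifest, path: str) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_manifest(path: str) -> CohortManifest:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read manifest {path}: {exc}") from exc
    return CohortManifest.from_frame(df)


def write_roi_annotations(rois: Iterable[RoiAnnotation], path: str) -> None:
    rows = []
    for roi in rois:
        for (x, y) in sorted(roi.pixels):
            rows.append((roi.sample_id, roi.roi_id, roi.label, x, y))
    pd.DataFrame(rows, columns=list(ROI_CSV_COLUMNS)).to_csv(path, index=False)


def read_roi_annotations(
    path: str,
    cohort: Optional[Mapping[str, NoduleSample]] = None,
) -> list[RoiAnnotation]:
    """Read ROI annotations, validating against the cohort's rasters.

    ``cohort`` maps sample_id to its sample; when given, every ROI pixel must
    exist in the sample raster and ROIs within a sample must not overlap.
    Unknown CSV columns are preserved in the file but ignored here.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read ROI file {path}: {exc}") from exc
    missing = [c for c in ROI_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ROI file {path} is missing columns: {missing}")

    rois: list[RoiAnnotation] = []
    for (sample_id, roi_id), grp in df.groupby(["sample_id", "roi_id"], sort=False):
        label = str(grp["label"].iloc[0])
        pixels = frozenset(
            (int(x), int(y)) for x, y in zip(grp["x"], grp["y"])
        )
        rois.append(RoiAnnotation(roi_id=str(roi_id), sample_id=str(sample_id), label=label, pixels=pixels))

    if cohort is not None:
        by_sample: dict[str, list[RoiAnnotation]] = {}
        for roi in rois:
            by_sample.setdefault(roi.sample_id, []).append(roi)
        for sid, sample_rois in by_sample.items():
            if sid not in cohort:
                raise RoiValidationError(f"ROI file references unknown sample {sid!r}")
            sample = cohort[sid]
            coords = {p.coord for p in sample.pixels}
            claimed: dict = {}
            for roi in sample_rois:
                outside = roi.pixels - coords
                if outside:
                    raise RoiValidationError(
                        f"ROI {roi.roi_id!r} pixel {sorted(outside)[0]} is outside "
                        f"the raster of sample {sid!r}"
                    )
                for p in roi.pixels:
                    if p in claimed:
                        raise RoiValidationError(
                            f"ROIs {claimed[p]!r} and {roi.roi_id!r} overlap at {p} "
                            f"in sample {sid!r}"
                        )
                    claimed[p] = roi.roi_id
    return rois


# ---------------------------------------------------------------------------
# Pixel class maps
# ---------------------------------------------------------------------------

def write_pixel_class_map(
    sample: NoduleSample,
    calls: Mapping[tuple, str],
    path: str,
) -> None:
    """Render per-pixel class calls as a PNG raster (HP green, HT yellow,
    PTC red; unclassified pixels transparent)."""
    from PIL import Image

    coords = {p.coord for p in sample.pixels}
    unknown = [c for c in calls if tuple(c) not in coords]
    if unknown:
        raise ParameterError(
            f"class call for pixel {unknown[0]} not present in sample "
            f"{sample.sample_id!r}"
        )
    bad = [lab for lab in calls.values() if lab not in CLASS_COLORS]
    if bad:
        raise ParameterError(f"unknown class label {bad[0]!r} in calls")

    w, h = sample.raster_shape()
    w, h = max(w, 1), max(h, 1)
    arr = np.zeros((h, w, 4), dtype=np.uint8)
    arr[:, :] = _BACKGROUND
    for (x, y), lab in calls.items():
        arr[int(y) - 1, int(x) - 1] = CLASS_COLORS[lab]
    Image.fromarray(arr, mode="RGBA").save(path, format="PNG")


def read_pixel_class_map_counts(path: str) -> dict:
    """Count class-colored pixels in a class-map PNG (inverse convenience)."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("RGBA"))
    counts = {}
    for lab, color in CLASS_COLORS.items():
        counts[lab] = int(np.all(arr == np.array(color, dtype=np.uint8), axis=-1).sum())
    return counts


def write_cohort(
    samples: Sequence[NoduleSample],
    manifest: CohortManifest,
    out_dir: str,
    mode: str = "continuous",
) -> None:
    """Persist a cohort as per-sample imzML files plus manifest and ROI CSVs."""
    os.makedirs(out_dir, exist_ok=True)
    records = []
    all_rois: list[RoiAnnotation] = []
    by_id = {r.sample_id: r for r in manifest}
    for sample in samples:
        fname = f"{sample.sample_id}.imzML"
        write_imzml(sample.pixels, os.path.join(out_dir, sample.sample_id), mode=mode)
        all_rois.extend(sample.rois)
        rec = by_id.get(sample.sample_id)
        if rec is None:
            warnings.warn(f"sample {sample.sample_id!r} absent from manifest")
            continue
        records.append(
            type(rec)(**{**vars(rec), "path": fname})
        )
    write_manifest(CohortManifest(records), os.path.join(out_dir, "manifest.csv"))
    write_roi_annotations(all_rois, os.path.join(out_dir, "rois.csv"))
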