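"""Volumes, annotations and sample tables: the package's I/O layer.

Conventions fixed here and relied on everywhere else:

* volumes are stored Z-major, ``values[slice, row, col]``, with spacing
  ``(dz, dy, dx)`` in millimetres;
* all pixel/voxel coordinates are 0-based ``(slice, row, col)``;
* region-of-interest (ROI) annotations are 2D: one labelled pixel set on a
  single axial slice, carrying one of the six tissue-pattern classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from scipy import ndimage

__all__ = [
    "Modality",
    "Units",
    "TissueClass",
    "CLINICAL_CLASSES",
    "Volume3D",
    "RoiAnnotation",
    "read_volume",
    "write_volume",
    "read_roi_labels",
    "rois_from_label_array",
    "write_sample_table",
    "read_sample_table",
    "SAMPLE_TABLE_META_COLUMNS",
]


class Modality(str, enum.Enum):
    CT = "CT"
    SPECT = "SPECT"


class Units(str, enum.Enum):
    HU = "HU"
    COUNTS = "counts"
    NORMALIZED = "normalized"


class TissueClass(enum.IntEnum):
    """Six tissue-pattern classes.

    Classes 1-3 are the clinical targets; 4-6 are extra categories included
    at training time to keep the classifier from forcing every window into a
    clinical class.
    """

    HEALTHY = 1
    PE = 2
    PNEUMONIA = 3
    ABNORMAL_CT_LOW_PERF = 4
    BACKGROUND = 5
    BODY_TISSUE = 6


#: the three classes reported in diagnostic metrics
CLINICAL_CLASSES = (TissueClass.HEALTHY, TissueClass.PE, TissueClass.PNEUMONIA)


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel spacing and modality metadata."""

    values: np.ndarray  # (Z, Y, X), float
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm
    modality: Modality
    units: Units

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.modality = Modality(self.modality)
        self.units = Units(self.units)
        if self.modality is Modality.CT and self.values.min() < -1100:
            raise ValueError(
                f"CT volume has implausible HU minimum {self.values.min():.1f} < -1100"
            )
        if self.modality is Modality.SPECT and self.units is Units.COUNTS and self.values.min() < 0:
            raise ValueError("SPECT count volume has negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 (dz * dy * dx)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_values(self, values: np.ndarray, units: Units | None = None) -> "Volume3D":
        return Volume3D(values, self.spacing, self.modality, units or self.units)


@dataclass
class RoiAnnotation:
    """An expert-annotated 2D region of one tissue pattern on one slice."""

    patient_id: str
    roi_id: int
    slice_index: int
    pixels: frozenset  # of (row, col)
    label: TissueClass

    def __post_init__(self) -> None:
        self.pixels = frozenset((int(r), int(c)) for r, c in self.pixels)
        if not self.pixels:
            raise ValueError("ROI has no pixels")
        self.label = TissueClass(self.label)

    def __len__(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        m[list(rows), list(cols)] = True
        return m


# ---------------------------------------------------------------------------
# volume reading / writing
# ---------------------------------------------------------------------------

_SLICE_SPACING_RTOL = 0.01


def _read_dicom_series(path: Path, modality: Modality) -> Volume3D:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".txt")
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise IOError(f"no DICOM files found in {path}")

    def z_of(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    zs = np.array([z_of(ds) for ds in datasets], dtype=float)
    if len(zs) < 2:
        raise IOError(f"DICOM series in {path} has fewer than 2 slices")
    gaps = np.diff(zs)
    if gaps.min() <= 0:
        raise IOError(f"DICOM series in {path} has duplicate or unsorted slice positions")
    if (gaps.max() - gaps.min()) > _SLICE_SPACING_RTOL * gaps.mean():
        raise IOError(
            "non-uniform slice spacing in DICOM series: gaps range "
            f"{gaps.min():.4f}-{gaps.max():.4f} mm"
        )
    dz = float(gaps.mean())
    first = datasets[0]
    dy, dx = (float(v) for v in first.PixelSpacing)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    values = np.stack(slices, axis=0)
    units = Units.HU if modality is Modality.CT else Units.COUNTS
    return Volume3D(values, (dz, dy, dx), modality, units)


def _read_nifti(path: Path, modality: Modality, units: Units | None) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise IOError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    # nibabel is (X, Y, Z); internal layout is (Z, Y, X)
    values = np.transpose(data, (2, 1, 0))
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    if units is None:
        units = Units.HU if modality is Modality.CT else Units.COUNTS
    return Volume3D(values, (dz, dy, dx), modality, units)


def read_volume(path: str | Path, modality: Modality | str, units: Units | None = None) -> Volume3D:
    """Read a volume from a DICOM series directory or a NIfTI file.

    CT rescale slope/intercept from DICOM headers is applied so CT values are
    Hounsfield units. Slices are sorted by patient z position; a non-uniform
    slice gap beyond 1% of the mean gap is an error.
    """
    path = Path(path)
    modality = Modality(modality)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if path.is_dir():
        return _read_dicom_series(path, modality)
    return _read_nifti(path, modality, units)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (spacing preserved in the header zooms)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.transpose(volume.values, (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# ROI annotations
# ---------------------------------------------------------------------------


def rois_from_label_array(
    labels: np.ndarray, patient_id: str = "unknown"
) -> list[RoiAnnotation]:
    """Split an integer label volume into per-slice connected-component ROIs.

    ``labels`` is on the CT grid, 0 = unlabelled, 1-6 = tissue-class codes.
    Each 8-connected same-label component within a slice becomes one ROI;
    same-label components on different slices are distinct ROIs (annotations
    are 2D). ``roi_id`` is assigned in (slice, label, component) order and is
    unique per patient.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"label volume must be 3D, got shape {labels.shape}")
    present = np.unique(labels)
    bad = [int(v) for v in present if v not in range(0, 7)]
    if bad:
        raise ValueError(f"label codes outside 0..6: {bad}")

    structure = np.ones((3, 3), dtype=int)  # 8-connectivity in-plane
    rois: list[RoiAnnotation] = []
    roi_id = 0
    for z in range(labels.shape[0]):
        sl = labels[z]
        for code in sorted(int(v) for v in np.unique(sl) if v != 0):
            comp, n = ndimage.label(sl == code, structure=structure)
            for k in range(1, n + 1):
                rows, cols = np.nonzero(comp == k)
                rois.append(
                    RoiAnnotation(
                        patient_id=patient_id,
                        roi_id=roi_id,
                        slice_index=z,
                        pixels=frozenset(zip(rows.tolist(), cols.tolist())),
                        label=TissueClass(code),
                    )
                )
                roi_id += 1
    return rois


def read_roi_labels(path: str | Path, patient_id: str | None = None) -> list[RoiAnnotation]:
    """Read a NIfTI label volume and return per-slice connected-component ROIs."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    labels = np.transpose(data, (2, 1, 0)).astype(np.int64)
    if patient_id is None:
        patient_id = path.name.split(".")[0]
    return rois_from_label_array(labels, patient_id=patient_id)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

SAMPLE_TABLE_META_COLUMNS = [
    "patient_id",
    "roi_id",
    "slice_index",
    "row",
    "col",
    "window_side",
    "label",
]


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    """Write a sample/feature table as TSV (lossless float round-trip).

    The table must contain the metadata columns (patient, ROI, slice, centre
    row/col, window side, label) followed by the feature columns; feature
    columns must be a consistent set for every row (pandas enforces this).
    """
    missing = [c for c in SAMPLE_TABLE_META_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    feature_cols = [c for c in samples.columns if c not in SAMPLE_TABLE_META_COLUMNS]
    if samples[feature_cols].isna().any().any():
        raise ValueError("sample table has missing feature values (ragged vectors?)")
    ordered = samples[SAMPLE_TABLE_META_COLUMNS + feature_cols]
    ordered.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_TABLE_META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a sample table, in stored order."""
    return [c for c in table.columns if c not in SAMPLE_TABLE_META_COLUMNS]
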