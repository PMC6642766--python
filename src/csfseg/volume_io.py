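"""Reading and writing CT volumes and binary CSF masks.

Volumes are held in memory as ``(slice, row, col)`` arrays — axis 0 is the
axial (inferior→superior) direction — together with voxel spacing in mm and
patient/exam identity. CT series are read from DICOM (Hounsfield units
reconstructed from the rescale slope/intercept tags, slices sorted by their
z position, never by filename); masks are exchanged as NIfTI-1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "MaskVolume",
    "GeometryError",
    "read_dicom_series",
    "read_volume_nifti",
    "write_volume_nifti",
    "read_mask_nifti",
    "write_mask_nifti",
]

#: tolerance (mm) when comparing voxel spacings of paired grids
SPACING_ATOL = 1e-3


class GeometryError(ValueError):
    """Raised when volume geometry is missing, inconsistent, or mismatched."""


@dataclass
class CTVolume:
    """A 3D CT examination in Hounsfield units.

    Attributes
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values; axis 0 runs inferior→superior.
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm, all strictly positive.
    patient_id, exam_id : str
        Identity used for patient-grouped cross-validation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""
    exam_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class MaskVolume:
    """A binary CSF mask aligned voxel-for-voxel to a :class:`CTVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""
    exam_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={labels.ndim}")
        uniq = np.unique(labels)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {uniq[:8]}")
        self.labels = labels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def with_labels(self, labels: np.ndarray) -> "MaskVolume":
        """A copy of this mask carrying new label data on the same grid."""
        return replace(self, labels=labels)


# ---------------------------------------------------------------------------
# DICOM

def read_dicom_series(directory_path: str | os.PathLike) -> CTVolume:
    """Read one axial CT series from a directory of single-frame DICOM files.

    Slices are sorted by ascending z of ``ImagePositionPatient`` (filename
    order is ignored); raw stored values are converted to HU with the rescale
    slope/intercept tags. Pixel spacing and the inter-slice distance define
    ``spacing``; for a single-slice series the slice thickness tag is used.
    """
    directory_path = os.fspath(directory_path)
    paths = sorted(
        os.path.join(directory_path, f)
        for f in os.listdir(directory_path)
        if not f.startswith(".")
    )
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(p)
        except pydicom.errors.InvalidDicomError:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((p, ds))
    if not datasets:
        raise FileNotFoundError(f"no DICOM image files found in {directory_path}")

    def z_of(item):
        _, ds = item
        if "ImagePositionPatient" not in ds:
            raise GeometryError(f"{item[0]}: missing ImagePositionPatient tag")
        return float(ds.ImagePositionPatient[2])

    datasets.sort(key=z_of)

    first_path, first = datasets[0]
    if "PixelSpacing" not in first:
        raise GeometryError(f"{first_path}: missing PixelSpacing tag")
    dy, dx = (float(v) for v in first.PixelSpacing)

    zs = [z_of(item) for item in datasets]
    if len(zs) > 1:
        dz = float(np.mean(np.diff(zs)))
        if dz <= 0:
            raise GeometryError("slice z positions are not strictly increasing")
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise GeometryError(f"{first_path}: single slice without SliceThickness")

    shape0 = first.pixel_array.shape
    slices = []
    for p, ds in datasets:
        arr = ds.pixel_array
        if arr.shape != shape0:
            raise GeometryError(
                f"{p}: slice shape {arr.shape} differs from first slice {shape0}"
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr.astype(np.float64) * slope + intercept)

    voxels = np.stack(slices, axis=0).astype(np.float32)
    return CTVolume(
        voxels=voxels,
        spacing=(dz, dy, dx),
        patient_id=str(getattr(first, "PatientID", "")),
        exam_id=str(getattr(first, "SeriesInstanceUID", "")),
    )


# ---------------------------------------------------------------------------
# NIfTI
#
# On disk NIfTI stores (x, y, z) = (col, row, slice); in memory we use
# (slice, row, col), so arrays are transposed on the way through. Volumes are
# brought to RAS+ ("closest canonical") orientation before the transpose so
# axis 0 always runs inferior→superior.


def _canonical_array_and_spacing(img) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NIfTI image, got shape {data.shape}")
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    return data.T, (dz, dy, dx)


def _to_nifti(array_zyx: np.ndarray, spacing) -> nib.Nifti1Image:
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    return nib.Nifti1Image(np.asarray(array_zyx).T, affine)


def read_volume_nifti(path, patient_id: str = "", exam_id: str = "") -> CTVolume:
    """Read a CT volume (HU) from a NIfTI file."""
    data, spacing = _canonical_array_and_spacing(nib.load(os.fspath(path)))
    return CTVolume(
        voxels=data.astype(np.float32),
        spacing=spacing,
        patient_id=patient_id,
        exam_id=exam_id,
    )


def write_volume_nifti(volume: CTVolume, path) -> None:
    nib.save(_to_nifti(volume.voxels.astype(np.float32), volume.spacing), os.fspath(path))


def read_mask_nifti(path, reference: CTVolume | None = None) -> MaskVolume:
    """Read a binary CSF mask, optionally checking geometry against a CT volume.

    Stored values are binarized (``> 0.5`` → 1). When ``reference`` is given,
    grid shape must match exactly and spacing within ``SPACING_ATOL`` mm.
    """
    data, spacing = _canonical_array_and_spacing(nib.load(os.fspath(path)))
    labels = (data > 0.5).astype(np.uint8)
    if reference is not None:
        if labels.shape != reference.shape:
            raise GeometryError(
                f"mask grid {labels.shape} does not match reference {reference.shape}"
            )
        if not np.allclose(spacing, reference.spacing, atol=SPACING_ATOL):
            raise GeometryError(
                f"mask spacing {spacing} does not match reference {reference.spacing}"
            )
        return MaskVolume(
            labels=labels,
            spacing=reference.spacing,
            patient_id=reference.patient_id,
            exam_id=reference.exam_id,
        )
    return MaskVolume(labels=labels, spacing=spacing)


def write_mask_nifti(mask: MaskVolume, path) -> None:
    """Write a mask as uint8 NIfTI; round-trips voxel-for-voxel."""
    nib.save(_to_nifti(mask.labels.astype(np.uint8), mask.spacing), os.fspath(path))
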