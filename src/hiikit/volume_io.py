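"""Reading and writing CT volumes and binary masks.

Volumes are held as plain 3D arrays of Hounsfield units with per-axis voxel
spacing in millimetres. The internal axis convention is (slice, row, column),
with ``spacing_mm`` in the same order; all downstream geometry works in
physical mm coordinates, so the convention never leaks into results.
Orientation matrices (gantry tilt, oblique acquisitions) are deliberately not
applied: the shape index depends on surface area and volume, which need
spacing, not pose.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import pydicom

__all__ = [
    "CTVolume",
    "BinaryMask",
    "FormatError",
    "AlignmentError",
    "read_nifti",
    "read_dicom_series",
    "write_volume",
    "write_mask",
]

# plausible HU range after rescale (12-bit CT convention)
HU_MIN, HU_MAX = -1024.0, 3071.0


class FormatError(ValueError):
    """Input file or series does not match the expected format."""


class AlignmentError(ValueError):
    """Two grids that must share shape/spacing do not."""


def _check_spacing(spacing_mm: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive components, got {spacing_mm!r}")
    return spacing


@dataclass
class CTVolume:
    """A 3D scalar CT grid in Hounsfield units.

    Axes are ordered (slice, row, column); ``spacing_mm`` follows the same
    order. ``origin_mm`` is the physical position of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order_note: str = "(slice, row, column); spacing in the same order"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected 3 axes, got {self.voxels.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class BinaryMask:
    """A {0,1} labelling aligned to a :class:`CTVolume` grid."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise FormatError(f"expected 3 axes, got {arr.ndim}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


def _affine_for(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def read_nifti(path: str | os.PathLike) -> CTVolume:
    """Read a 3D NIfTI volume; values are passed through unchanged (assumed HU).

    Spacing comes from the header zooms; the on-disk axis order is kept.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise FormatError(f"{path}: expected a 3D scalar volume, got {len(shape)} dimensions {shape}")
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()[:3]
    origin = tuple(np.asarray(img.affine)[:3, 3])
    return CTVolume(voxels=data, spacing_mm=tuple(zooms), origin_mm=origin)


def read_mask_nifti(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI label map as a binary mask (any nonzero voxel is 1)."""
    vol = read_nifti(path)
    return BinaryMask(
        voxels=(vol.voxels > 0.5).astype(np.uint8),
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
    )


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume as int16 NIfTI (HU fit 16-bit losslessly)."""
    data = np.asarray(volume.voxels)
    if np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_for(volume.spacing_mm, volume.origin_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a BinaryMask as uint8 NIfTI; round trips losslessly."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_for(mask.spacing_mm, mask.origin_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def read_dicom_series(directory: str | os.PathLike) -> CTVolume:
    """Read one axial CT series stored as per-slice DICOM files.

    Slices are sorted by spatial position along the slice normal (falling back
    to InstanceNumber when positions are absent). HU values are
    ``stored * RescaleSlope + RescaleIntercept``; missing rescale tags are an
    error rather than a silent slope-1 assumption, because a wrong intercept
    shifts the 40-100 HU segmentation window catastrophically.
    """
    directory = str(directory)
    if not os.path.isdir(directory):
        raise FileNotFoundError(directory)
    paths = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if not f.startswith(".")
    )
    datasets = []
    for p in paths:
        if os.path.isdir(p):
            continue
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR leftovers)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"{directory}: no DICOM image files found")

    uids = sorted({str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets})
    if len(uids) > 1:
        raise FormatError(f"{directory}: multiple series present, SeriesInstanceUIDs: {uids}")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            orient = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
            row, col = np.array(orient[:3], float), np.array(orient[3:], float)
            normal = np.cross(row, col)
            return float(np.dot(np.array(pos, float), normal))
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    slices = []
    for ds in datasets:
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            raise FormatError(
                "missing RescaleSlope/RescaleIntercept; refusing to guess HU scaling"
            )
        slices.append(ds.pixel_array.astype(np.float64) * float(slope) + float(intercept))
    voxels = np.stack(slices, axis=0)

    ps = getattr(datasets[0], "PixelSpacing", None)
    if ps is None:
        raise FormatError("missing PixelSpacing tag")
    row_mm, col_mm = float(ps[0]), float(ps[1])

    if len(datasets) > 1 and hasattr(datasets[0], "ImagePositionPatient"):
        zs = np.array([sort_key(ds) for ds in datasets])
        slice_mm = float(np.median(np.diff(zs)))
    else:
        slice_mm = float(getattr(datasets[0], "SliceThickness", 1.0))
    origin = tuple(float(v) for v in getattr(datasets[0], "ImagePositionPatient", (0, 0, 0)))
    return CTVolume(voxels=voxels, spacing_mm=(abs(slice_mm), row_mm, col_mm), origin_mm=origin)
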