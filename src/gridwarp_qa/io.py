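"""Volume input/output and pre-processing: DICOM series reading, NIfTI
round-trips, cropping and CT housing masking.

No resampling happens in this module: cropping and masking preserve the
world coordinates of every retained voxel exactly.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage

from .volume import DeformationField, ImageVolume

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_field",
    "write_field",
    "read_dicom_series",
    "CropBox",
    "crop",
    "mask_housing",
]


# ---------------------------------------------------------------- NIfTI

def _geometry_from_affine(affine: np.ndarray):
    m = np.asarray(affine, dtype=float)[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("affine encodes non-positive spacing")
    direction = m / spacing
    origin = np.asarray(affine, dtype=float)[:3, 3]
    return tuple(spacing), tuple(origin), direction


def read_nifti(path) -> ImageVolume:
    """Read a 3D scalar NIfTI volume. Non-3D inputs are rejected."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} in {path}")
    spacing, origin, direction = _geometry_from_affine(img.affine)
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, origin=origin, direction=direction)


def write_nifti(vol: ImageVolume, path) -> pathlib.Path:
    path = pathlib.Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_field(path) -> DeformationField:
    """Read a 3-component displacement field stored as a 4D NIfTI (world mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector-intent layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"expected a (nx, ny, nz, 3) displacement field, got {data.shape}")
    spacing, origin, direction = _geometry_from_affine(img.affine)
    return DeformationField(data=np.asarray(data, dtype=float), spacing=spacing, origin=origin, direction=direction)


def write_field(field: DeformationField, path) -> pathlib.Path:
    path = pathlib.Path(path)
    img = nib.Nifti1Image(np.asarray(field.data, dtype=np.float64), field.affine)
    img.header.set_xyzt_units("mm")
    img.header["intent_code"] = 1007  # NIFTI_INTENT_VECTOR
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------- DICOM

def read_dicom_series(directory) -> ImageVolume:
    """Read a single-series DICOM directory into an :class:`ImageVolume`.

    Slices are sorted by position along the slice normal (not by filename);
    mixed series and missing slices (slice-gap non-uniformity above 1%)
    raise explicit errors.  Geometry is converted from the DICOM LPS
    patient frame to the internal NIfTI RAS frame.
    """
    directory = pathlib.Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM image files in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise ValueError(f"directory contains {len(uids)} DICOM series; expected exactly one")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in slices])
    order = np.argsort(positions @ normal)
    slices = [slices[i] for i in order]
    positions = positions[order]

    proj = positions @ normal
    gaps = np.diff(proj)
    if len(gaps) == 0:
        raise ValueError("series contains a single slice; a 3D volume is required")
    if np.any(gaps <= 0):
        raise ValueError("duplicate or non-monotonic slice positions in series")
    mean_gap = float(np.mean(gaps))
    if np.max(np.abs(gaps - mean_gap)) > 0.01 * mean_gap:
        raise ValueError(
            f"non-uniform slice spacing (gaps {gaps.min():.4g}..{gaps.max():.4g} mm); "
            "the series appears to have missing slices"
        )

    def _pixels(ds):
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + inter

    # pixel_array is (row, col); internal index i runs along row_dir (columns)
    data = np.stack([_pixels(ds).T for ds in slices], axis=2)
    row_spacing, col_spacing = (float(v) for v in slices[0].PixelSpacing)
    spacing = (col_spacing, row_spacing, mean_gap)
    slice_dir = (positions[-1] - positions[0]) / (proj[-1] - proj[0])
    direction = np.column_stack([row_dir, col_dir, slice_dir])
    origin = positions[0]

    # LPS (DICOM) -> RAS (internal/NIfTI): flip the first two world axes
    flip = np.diag([-1.0, -1.0, 1.0])
    return ImageVolume(
        data=data,
        spacing=spacing,
        origin=tuple(flip @ origin),
        direction=flip @ direction,
    )


# ---------------------------------------------------------------- crop

@dataclass
class CropBox:
    """Inclusive per-axis voxel index ranges, e.g. ``CropBox(((8, 87),)*3)``."""

    ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        self.ranges = tuple((int(lo), int(hi)) for lo, hi in self.ranges)
        for lo, hi in self.ranges:
            if hi < lo:
                raise ValueError(f"empty crop range {lo}:{hi}")
            if lo < 0:
                raise ValueError("crop indices must be non-negative")

    @classmethod
    def parse(cls, text: str) -> "CropBox":
        """Parse ``"x0:x1,y0:y1,z0:z1"`` (inclusive bounds)."""
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError("crop box must have three comma-separated ranges")
        return cls(tuple(tuple(int(v) for v in p.split(":")) for p in parts))

    def check_within(self, shape):
        for ax, ((lo, hi), n) in enumerate(zip(self.ranges, shape)):
            if hi >= n:
                raise ValueError(f"crop range {lo}:{hi} exceeds axis {ax} extent {n}")

    @property
    def slices(self):
        return tuple(slice(lo, hi + 1) for lo, hi in self.ranges)


def crop(vol: ImageVolume, box: CropBox) -> ImageVolume:
    """Crop to the box; the origin is shifted so retained voxels keep their
    world coordinates exactly."""
    box.check_within(vol.grid_shape)
    data = vol.data[box.slices].copy()
    first = [lo for lo, _ in box.ranges]
    origin = tuple(np.atleast_1d(vol.index_to_world(first)))
    return ImageVolume(data=data, spacing=vol.spacing, origin=origin, direction=vol.direction)


# ---------------------------------------------------------------- masking

def mask_housing(
    ct: ImageVolume,
    strategy: str = "intensity_band",
    band: tuple[float, float] | None = None,
    background: float = 0.0,
    body_threshold: float | None = None,
    erosion_mm: float | None = None,
) -> ImageVolume:
    """Remove the phantom's outer housing from a CT volume.

    The housing shell is visible on CT but not on MR, and left in place it
    drags the deformable registration at the phantom rim.  Two strategies:

    - ``intensity_band``: voxels with intensity in ``band`` (inclusive) are
      replaced by ``background``.
    - ``erode_body_outline``: the foreground (above ``body_threshold``,
      default Otsu) is eroded by ``erosion_mm``; foreground voxels outside
      the eroded outline are replaced by ``background``.
    """
    data = np.array(ct.data, dtype=float)
    if strategy == "intensity_band":
        if band is None:
            raise ValueError("intensity_band strategy requires band=(lo, hi)")
        lo, hi = band
        data[(ct.data >= lo) & (ct.data <= hi)] = background
    elif strategy == "erode_body_outline":
        if body_threshold is None:
            from skimage.filters import threshold_otsu

            body_threshold = float(threshold_otsu(ct.data))
        if erosion_mm is None:
            raise ValueError("erode_body_outline strategy requires erosion_mm")
        fg = ct.data > body_threshold
        labels, n = ndimage.label(fg)
        if n == 0:
            raise ValueError("no foreground above body_threshold")
        largest = np.argmax(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))) + 1
        outline = labels == largest
        filled = ndimage.binary_fill_holes(outline)
        iters = max(1, int(round(erosion_mm / min(ct.spacing))))
        eroded = ndimage.binary_erosion(filled, iterations=iters)
        data[fg & ~eroded] = background
    else:
        raise ValueError(f"unknown masking strategy {strategy!r}")

    if not np.any(data > background):
        raise ValueError("housing masking removed all foreground; check the parameters")
    return ImageVolume(data=data, spacing=ct.spacing, origin=ct.origin, direction=ct.direction)
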