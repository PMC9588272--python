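"""Shared fixtures: a small synthetic phantom pair and helpers.

Expensive artefacts (rasterised volumes, registrations) are session-scoped
so the suite builds each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from gridwarp_qa.io import mask_housing
from gridwarp_qa.registration import RegistrationConfig, bspline_register
from gridwarp_qa.synthetic import (
    DistortionModel,
    PhantomSpec,
    build_phantom_ct,
    build_phantom_mr,
)

SMALL_SHAPE = (48, 48, 48)
SMALL_SPACING = 4.0


def small_phantom_spec() -> PhantomSpec:
    return PhantomSpec(
        body_diameter=170.0,
        body_length=180.0,
        grid_shape=(3, 3, 3),
        grid_spacing=50.0,
        marker_radius=8.0,
        housing_thickness=6.0,
    )


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_ct(small_spec):
    return build_phantom_ct(small_spec, shape=SMALL_SHAPE, spacing=SMALL_SPACING)


@pytest.fixture(scope="session")
def small_ct_masked(small_spec, small_ct):
    return mask_housing(
        small_ct,
        strategy="erode_body_outline",
        body_threshold=40.0,
        erosion_mm=small_spec.housing_thickness + 2 * SMALL_SPACING,
    )


@pytest.fixture(scope="session")
def body_mask(small_ct_masked):
    return small_ct_masked.data > 10.0


@pytest.fixture(scope="session")
def radial_model() -> DistortionModel:
    # 2% linear radial warp: 1 mm at 50 mm, 1.73 mm at the corner markers
    return DistortionModel(radial_coeffs=(0.02, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_mr(small_spec, radial_model):
    return build_phantom_mr(small_spec, radial_model, shape=SMALL_SHAPE, spacing=SMALL_SPACING)


@pytest.fixture(scope="session")
def small_mr_undistorted(small_spec):
    return build_phantom_mr(
        small_spec, DistortionModel(), shape=SMALL_SHAPE, spacing=SMALL_SPACING
    )


@pytest.fixture(scope="session")
def reg_config() -> RegistrationConfig:
    return RegistrationConfig(
        control_point_spacing=24.0, pyramid_levels=2, max_iterations=80
    )


@pytest.fixture(scope="session")
def recovered_field(small_mr, small_ct_masked, reg_config, body_mask):
    """First-pass registration of the distorted MR to the masked CT."""
    return bspline_register(small_mr, small_ct_masked, reg_config, fixed_mask=body_mask)


def write_dicom_series(directory, n_slices=10, shape=(16, 16), spacing=(1.2, 0.8),
                       slice_gap=2.5, origin=(-10.0, -5.0, 3.0), series_uid=None,
                       value_offset=0.0, prefix="slice"):
    """Write a tiny synthetic single-series DICOM directory (test fixture;
    the package itself never writes DICOM)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    rows, cols = shape
    paths = []
    for k in range(n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.Rows, ds.Columns = rows, cols
        ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]  # row, col spacing
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [origin[0], origin[1], origin[2] + k * slice_gap]
        ds.InstanceNumber = k + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        arr = (np.arange(rows * cols).reshape(rows, cols) + 100 * k + value_offset)
        ds.PixelData = arr.astype(np.uint16).tobytes()
        p = directory / f"{prefix}_{n_slices - k:03d}.dcm"  # filenames reverse-ordered
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths
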