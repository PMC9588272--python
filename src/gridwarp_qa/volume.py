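"""Physical-space image containers.

Everything downstream of I/O speaks :class:`ImageVolume` (scalar voxels) or
:class:`DeformationField` (one millimetre displacement vector per voxel).
Both carry the full affine geometry — spacing, origin and axis direction
cosines — so world coordinates survive cropping, registration and sampling.

Conventions
-----------
* Arrays are indexed ``[i, j, k]`` and the world coordinate of voxel
  ``(i, j, k)`` is ``origin + direction @ (spacing * (i, j, k))`` in mm.
* The internal world frame follows the NIfTI (RAS) convention; DICOM input
  is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageVolume", "DeformationField"]

_ORTHO_TOL = 1e-6


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-5):
        raise ValueError("direction matrix must be orthonormal")
    if abs(abs(np.linalg.det(d)) - 1.0) > 1e-4:
        raise ValueError("direction matrix must have |det| = 1")
    return d


@dataclass
class _Grid:
    """Shared voxel-grid geometry for scalar and vector volumes."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.direction = _as_direction(self.direction)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI style)."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = (self.direction @ (np.asarray(self.spacing) * ijk).T).T + self.origin
        return xyz.squeeze()

    def world_to_index(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        ijk = (self.direction.T @ (xyz - self.origin).T).T / np.asarray(self.spacing)
        return ijk.squeeze()

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the volume's geometric center."""
        c = (np.asarray(self.grid_shape, dtype=float) - 1.0) / 2.0
        return np.atleast_1d(self.index_to_world(c))

    def same_grid(self, other: "_Grid", atol: float = 1e-6) -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def geometry_like(self) -> dict:
        return dict(spacing=self.spacing, origin=self.origin, direction=self.direction.copy())


@dataclass
class ImageVolume(_Grid):
    """A 3D scalar image with physical geometry."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got ndim={self.data.ndim}")

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the volume shape")
        return replace(self, data=np.asarray(data))


@dataclass
class DeformationField(_Grid):
    """Dense displacement field on a fixed-image grid.

    ``data[i, j, k]`` is the world-mm displacement ``u(x)`` such that the
    moving image is read at ``x + u(x)`` for the fixed-grid voxel at world
    position ``x``.  Same sign convention as the per-marker distortion
    vectors reported downstream.
    """

    #: optimiser diagnostics (bending energy, metric values); not serialised
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        super().__post_init__()
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(
                f"DeformationField requires shape (nx, ny, nz, 3), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DeformationField must be finite everywhere")

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)
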