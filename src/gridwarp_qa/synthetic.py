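"""Synthetic CT/MR phantom simulator with known ground-truth distortion.

Emulates the class of rigid QA phantoms used for MRI geometric-distortion
measurements: a fluid-filled cylinder containing a regular 3D grid of
high-intensity markers visible on both CT and MR, inside an outer housing
that is visible on CT only.  The MR copy is warped by a smooth parametric
distortion field that grows with distance from isocenter — the signature of
gradient nonlinearity — plus an optional frequency-encode-axis term standing
in for B0 inhomogeneity.

Every simulated pair comes with an exact ground-truth table of marker
displacements, so registration and analysis accuracy can be scored without
a physical scanner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "DistortionModel",
    "build_phantom_ct",
    "build_phantom_mr",
    "true_marker_displacements",
    "marker_positions",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "marker_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "ux_mm",
    "uy_mm",
    "uz_mm",
    "magnitude_mm",
    "r_mm",
]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class PhantomSpec:
    """Geometry and contrast of a cylindrical grid-marker phantom.

    All lengths in mm.  The cylinder axis is z; the marker grid is centered
    on the phantom center (== scanner isocenter when positioned by lasers).

    Parameters
    ----------
    body_diameter, body_length
        Outer dimensions of the fluid-filled body cylinder.
    grid_shape
        Marker counts per axis, e.g. ``(7, 7, 7)``.
    grid_spacing
        Marker pitch per axis in mm (scalar broadcasts to all axes).
    marker_radius
        Sphere radius, or in-plane radius for cylindrical markers.
    marker_shape
        ``"sphere"`` or ``"cylinder"`` (long axis along z; cylindrical
        markers reduce susceptibility artefacts on real phantoms).
    marker_length
        Full length of cylindrical markers (default ``2 * marker_radius``).
    housing_thickness
        Outer acrylic shell, visible on CT only.
    """

    body_diameter: float = 360.0
    body_length: float = 360.0
    grid_shape: tuple[int, int, int] = (7, 7, 7)
    grid_spacing: tuple[float, float, float] | float = 40.0
    marker_radius: float = 8.0
    marker_shape: str = "sphere"
    marker_length: float | None = None
    housing_thickness: float = 8.0
    ct_intensities: dict = field(
        default_factory=lambda: dict(background=0.0, body=80.0, marker=1200.0, housing=500.0)
    )
    mr_intensities: dict = field(
        default_factory=lambda: dict(background=0.0, body=60.0, marker=1000.0)
    )

    def __post_init__(self):
        if np.isscalar(self.grid_spacing):
            self.grid_spacing = (float(self.grid_spacing),) * 3
        self.grid_spacing = tuple(float(s) for s in self.grid_spacing)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.marker_length is None:
            self.marker_length = 2.0 * self.marker_radius
        for name in ("body_diameter", "body_length", "marker_radius", "marker_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.housing_thickness < 0:
            raise ValueError("housing_thickness must be >= 0")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape counts must be >= 1")
        if self.marker_shape not in ("sphere", "cylinder"):
            raise ValueError(f"unknown marker_shape {self.marker_shape!r}")
        if min(self.grid_spacing) <= 2.0 * self.marker_radius and max(self.grid_shape) > 1:
            raise ValueError("grid_spacing must exceed 2*marker_radius (markers must not touch)")
        # marker grid must fit inside the body
        half = [(n - 1) / 2.0 * p for n, p in zip(self.grid_shape, self.grid_spacing)]
        rho_max = float(np.hypot(half[0], half[1]))
        z_half = self.marker_length / 2.0 if self.marker_shape == "cylinder" else self.marker_radius
        if rho_max + self.marker_radius > self.body_diameter / 2.0:
            raise ValueError("marker grid does not fit inside the body diameter")
        if half[2] + z_half > self.body_length / 2.0:
            raise ValueError("marker grid does not fit inside the body length")

    @property
    def n_markers(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def marker_volume_mm3(self) -> float:
        if self.marker_shape == "sphere":
            return 4.0 / 3.0 * np.pi * self.marker_radius**3
        return np.pi * self.marker_radius**2 * self.marker_length


@dataclass
class DistortionModel:
    """Smooth parametric ground-truth distortion field.

    The gradient-nonlinearity-like part is a radial polynomial with odd
    orders only, ``u_r(r) = c1*r + c3*r^3 + c5*r^5`` (r in mm from
    isocenter), directed radially outward.  The B0-like part displaces
    along the frequency-encode axis by ``b0_amplitude * (r / b0_reference_radius)**2``
    and flips sign when the encode polarity is reversed (use
    :meth:`reversed_polarity`).

    With ``zero_at_isocenter`` set (the physical default — distortion is
    minimal at the magnet center) the field evaluates to the zero vector at
    the isocenter; ``constant_offset`` must then be zero.
    """

    radial_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b0_amplitude: float = 0.0
    b0_reference_radius: float = 100.0
    frequency_axis: str = "x"
    zero_at_isocenter: bool = True
    constant_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.frequency_axis not in _AXIS_INDEX:
            raise ValueError("frequency_axis must be one of 'x', 'y', 'z'")
        self.radial_coeffs = tuple(float(c) for c in self.radial_coeffs) + (0.0,) * (
            3 - len(self.radial_coeffs)
        )
        self.constant_offset = tuple(float(c) for c in self.constant_offset)
        if self.zero_at_isocenter and any(c != 0.0 for c in self.constant_offset):
            raise ValueError("constant_offset must be zero when zero_at_isocenter is set")
        if self.b0_reference_radius <= 0:
            raise ValueError("b0_reference_radius must be > 0")

    def displacement(self, points, isocenter=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Evaluate u(x) in mm at world points (N, 3)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(isocenter, dtype=float)
        r = np.linalg.norm(p, axis=1)
        c1, c3, c5 = self.radial_coeffs
        ur = r * (c1 + r**2 * (c3 + r**2 * c5))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, p / np.where(r[:, None] == 0, 1.0, r[:, None]), 0.0)
        u = ur[:, None] * unit
        if self.b0_amplitude != 0.0:
            ax = _AXIS_INDEX[self.frequency_axis]
            u[:, ax] += self.b0_amplitude * (r / self.b0_reference_radius) ** 2
        u += np.asarray(self.constant_offset)
        return u

    def reversed_polarity(self) -> "DistortionModel":
        """The same field acquired with the frequency-encode direction flipped."""
        return DistortionModel(
            radial_coeffs=self.radial_coeffs,
            b0_amplitude=-self.b0_amplitude,
            b0_reference_radius=self.b0_reference_radius,
            frequency_axis=self.frequency_axis,
            zero_at_isocenter=self.zero_at_isocenter,
            constant_offset=self.constant_offset,
        )

    def is_zero(self) -> bool:
        return (
            all(c == 0 for c in self.radial_coeffs)
            and self.b0_amplitude == 0
            and all(c == 0 for c in self.constant_offset)
        )


def marker_positions(spec: PhantomSpec, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Analytic marker grid positions (N, 3) in world mm, row-major over (x, y, z)."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * p + c
        for n, p, c in zip(spec.grid_shape, spec.grid_spacing, center)
    ]
    pts = np.array(list(itertools.product(*axes)), dtype=float)
    return pts


def _nearest_marker_distance(points: np.ndarray, spec: PhantomSpec, center) -> np.ndarray:
    """Distance from each point to the surface of the nearest grid marker (signed)."""
    p = points - np.asarray(center, dtype=float)
    d = np.empty_like(p)
    for a in range(3):
        n, pitch = spec.grid_shape[a], spec.grid_spacing[a]
        idx = np.clip(np.round(p[:, a] / pitch + (n - 1) / 2.0), 0, n - 1)
        d[:, a] = p[:, a] - (idx - (n - 1) / 2.0) * pitch
    if spec.marker_shape == "sphere":
        return np.linalg.norm(d, axis=1) - spec.marker_radius
    rho = np.hypot(d[:, 0], d[:, 1])
    return np.maximum(rho - spec.marker_radius, np.abs(d[:, 2]) - spec.marker_length / 2.0)


def _phantom_fields(points: np.ndarray, spec: PhantomSpec, center):
    """Signed distances to body, housing outer surface, and nearest marker."""
    p = points - np.asarray(center, dtype=float)
    rho = np.hypot(p[:, 0], p[:, 1])
    z = np.abs(p[:, 2])
    d_body = np.maximum(rho - spec.body_diameter / 2.0, z - spec.body_length / 2.0)
    d_house = np.maximum(
        rho - (spec.body_diameter / 2.0 + spec.housing_thickness),
        z - (spec.body_length / 2.0 + spec.housing_thickness),
    )
    d_marker = _nearest_marker_distance(points, spec, center)
    return d_body, d_house, d_marker


def _hard_intensity(points, spec: PhantomSpec, modality: str, center) -> np.ndarray:
    d_body, d_house, d_marker = _phantom_fields(points, spec, center)
    levels = spec.ct_intensities if modality == "ct" else spec.mr_intensities
    out = np.full(points.shape[0], float(levels["background"]))
    if modality == "ct" and spec.housing_thickness > 0:
        out[(d_house <= 0) & (d_body > 0)] = float(levels["housing"])
    out[d_body <= 0] = float(levels["body"])
    out[(d_marker <= 0) & (d_body <= 0)] = float(levels["marker"])
    return out


def _boundary_distance(points, spec: PhantomSpec, modality: str, center) -> np.ndarray:
    d_body, d_house, d_marker = _phantom_fields(points, spec, center)
    dist = np.minimum(np.abs(d_body), np.abs(d_marker))
    if modality == "ct" and spec.housing_thickness > 0:
        dist = np.minimum(dist, np.abs(d_house))
    return dist


def _default_geometry(shape, spacing):
    shape = tuple(int(n) for n in shape)
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    # volume geometric center sits at world (0, 0, 0) == isocenter
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return shape, spacing, origin


def _check_fits(spec: PhantomSpec, shape, spacing, modality: str):
    extent = [n * s for n, s in zip(shape, spacing)]
    pad = spec.housing_thickness if modality == "ct" else 0.0
    need = (
        spec.body_diameter + 2 * pad,
        spec.body_diameter + 2 * pad,
        spec.body_length + 2 * pad,
    )
    for ax, (e, nd) in enumerate(zip(extent, need)):
        if nd > e + 1e-9:
            raise ValueError(
                f"phantom does not fit in the volume along axis {ax}: needs {nd:.1f} mm, "
                f"volume extent is {e:.1f} mm ({shape[ax]} voxels x {spacing[ax]:.2f} mm)"
            )


_SUPERSAMPLE_OFFSETS = np.array(list(itertools.product((-1 / 3, 0.0, 1 / 3), repeat=3)))


def _rasterise(spec, shape, spacing, origin, modality, point_map=None, center=(0, 0, 0)):
    """Partial-volume rasterisation: hard classification away from surfaces,
    3x3x3 supersampling of voxels whose (warped) center lies near a surface.

    ``point_map`` maps sample positions from the output image's world frame
    to the undistorted phantom frame (identity for CT)."""
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * np.asarray(spacing) + np.asarray(
        origin
    )
    pts = point_map(centers) if point_map is not None else centers
    vals = _hard_intensity(pts, spec, modality, center)
    near = _boundary_distance(pts, spec, modality, center) <= 0.75 * float(
        np.linalg.norm(spacing)
    )
    if np.any(near):
        sub_centers = centers[near]
        acc = np.zeros(sub_centers.shape[0])
        for off in _SUPERSAMPLE_OFFSETS:
            sp = sub_centers + off * np.asarray(spacing)
            spp = point_map(sp) if point_map is not None else sp
            acc += _hard_intensity(spp, spec, modality, center)
        vals[near] = acc / len(_SUPERSAMPLE_OFFSETS)
    return vals.reshape(shape)


def build_phantom_ct(
    spec: PhantomSpec,
    shape=(96, 96, 96),
    spacing=4.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    center=(0.0, 0.0, 0.0),
) -> ImageVolume:
    """Rasterise the reference CT: body + housing + markers, optional
    additive Gaussian noise.  Volume center is placed at world (0,0,0)."""
    shape, spacing, origin = _default_geometry(shape, spacing)
    _check_fits(spec, shape, spacing, "ct")
    data = _rasterise(spec, shape, spacing, origin, "ct", center=center)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def _inverse_warp(model: DistortionModel, points, isocenter, tol=0.01, max_iter=50) -> np.ndarray:
    """Solve y = x + u(x) for x by fixed-point iteration (per voxel).

    Inverse-mapping resampling: the MR image shows the content of the
    undistorted position x at the distorted position y = x + u(x)."""
    x = points.copy()
    for _ in range(max_iter):
        x_new = points - model.displacement(x, isocenter=isocenter)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


def build_phantom_mr(
    spec: PhantomSpec,
    model: DistortionModel,
    shape=(96, 96, 96),
    spacing=4.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    center=(0.0, 0.0, 0.0),
    isocenter=(0.0, 0.0, 0.0),
) -> ImageVolume:
    """Simulate the distorted MR acquisition of the phantom.

    The housing is omitted (visible on CT but not MR), the ideal phantom is
    resampled through the distortion warp, and Rician-like noise (magnitude
    of complex Gaussian noise) is added with the given seed."""
    shape, spacing, origin = _default_geometry(shape, spacing)
    _check_fits(spec, shape, spacing, "mr")

    if model.is_zero():
        point_map = None
    else:

        def point_map(pts):
            return _inverse_warp(model, pts, isocenter)

    data = _rasterise(spec, shape, spacing, origin, "mr", point_map=point_map, center=center)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, size=data.shape)
        n2 = rng.normal(0.0, noise_sigma, size=data.shape)
        data = np.hypot(data + n1, n2)
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def true_marker_displacements(
    spec: PhantomSpec,
    model: DistortionModel,
    center=(0.0, 0.0, 0.0),
    isocenter=(0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Ground-truth table: one row per grid marker with its CT centroid,
    displacement vector (the model evaluated at the centroid), magnitude and
    3D radial distance from isocenter."""
    pos = marker_positions(spec, center=center)
    u = model.displacement(pos, isocenter=isocenter)
    iso = np.asarray(isocenter, dtype=float)
    df = pd.DataFrame(
        {
            "marker_id": np.arange(len(pos)),
            "x_mm": pos[:, 0],
            "y_mm": pos[:, 1],
            "z_mm": pos[:, 2],
            "ux_mm": u[:, 0],
            "uy_mm": u[:, 1],
            "uz_mm": u[:, 2],
            "magnitude_mm": np.linalg.norm(u, axis=1),
            "r_mm": np.linalg.norm(pos - iso, axis=1),
        }
    )
    return df[GROUND_TRUTH_COLUMNS]
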