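"""Second-pass (residual) registration and the reliable-radius criterion.

A deformable registration can only recover warps that fit within its
control-point capture range; toward the phantom periphery the distortion
grows and the first pass under-recovers it.  Registering the *deformed*
MR to the CT a second time measures what the first pass missed: wherever
the residual field is above tolerance, the first-pass distortion numbers
are lower bounds, not measurements.  The reliable radius delineates the
region where they can be trusted.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .analysis import MarkerSet, compute_distortion
from .registration import RegistrationConfig, bspline_register
from .volume import DeformationField, ImageVolume

__all__ = ["ResidualReport", "residual_register", "reliable_radius", "residual_markers"]


def residual_register(
    deformed_mr: ImageVolume,
    ct: ImageVolume,
    config: RegistrationConfig | None = None,
    fixed_mask: np.ndarray | None = None,
) -> DeformationField:
    """Register the first-pass deformed MR to the CT a second time.

    Identical contract to :func:`gridwarp_qa.registration.bspline_register`;
    the returned field is the residual displacement the first pass failed
    to recover (near zero wherever the first pass succeeded).
    """
    return bspline_register(deformed_mr, ct, config=config, fixed_mask=fixed_mask)


def residual_markers(
    residual_field: DeformationField,
    ct_centroids: np.ndarray,
    isocenter=None,
    provenance: dict | None = None,
) -> MarkerSet:
    """Sample the residual field at the same CT marker centroids used for
    the first pass, so both fields are compared at identical points."""
    return compute_distortion(
        residual_field, ct_centroids, isocenter=isocenter, provenance=provenance
    )


def reliable_radius(
    residuals: MarkerSet,
    tolerance_mm: float,
    shell_width_mm: float = 10.0,
    min_fraction: float = 0.95,
) -> tuple[float, pd.DataFrame]:
    """Outer radius of the region where residuals stay within tolerance.

    Markers are grouped into radial shells of ``shell_width_mm``; scanning
    outward from the isocenter, the reliable radius is the outer edge of
    the last contiguous shell in which at least ``min_fraction`` of the
    markers have residual magnitude <= ``tolerance_mm`` (empty shells give
    no evidence and do not break the scan).  The radius is capped at the
    outer edge of the outermost populated shell.  Returns the radius and
    the per-shell fraction table; shells beyond the radius are the
    unreliable region.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be > 0")
    if shell_width_mm <= 0:
        raise ValueError("shell_width_mm must be > 0")
    r = residuals.table["r_mm"].to_numpy(dtype=float)
    mag = residuals.table["magnitude_mm"].to_numpy(dtype=float)
    n_shells = int(np.ceil(r.max() / shell_width_mm)) if len(r) else 0

    rows = []
    radius = 0.0
    failed = False
    for s in range(n_shells):
        lo, hi = s * shell_width_mm, (s + 1) * shell_width_mm
        sel = (r >= lo) & (r < hi)
        n = int(sel.sum())
        frac = float(np.mean(mag[sel] <= tolerance_mm)) if n else np.nan
        ok = (n == 0) or (frac >= min_fraction)
        rows.append(
            dict(lo_mm=lo, hi_mm=hi, n=n, fraction_within_tolerance=frac, passed=bool(ok))
        )
        if not failed:
            if not ok:
                failed = True
            elif n > 0:
                radius = hi
    if radius == 0.0:
        warnings.warn(
            "no radial shell satisfies the reliable-radius criterion; "
            "the first-pass registration cannot be trusted anywhere",
            stacklevel=2,
        )
    return radius, pd.DataFrame(rows)


@dataclass
class ResidualReport:
    """Residual-registration outcome: per-marker residuals, the reliable
    radius, and the per-shell pass fractions."""

    residuals: MarkerSet
    reliable_radius_mm: float
    tolerance_mm: float
    shell_width_mm: float
    shells: pd.DataFrame
    provenance: dict = dc_field(default_factory=dict)

    @classmethod
    def from_markers(
        cls,
        residuals: MarkerSet,
        tolerance_mm: float,
        shell_width_mm: float = 10.0,
        min_fraction: float = 0.95,
        provenance: dict | None = None,
    ) -> "ResidualReport":
        radius, shells = reliable_radius(residuals, tolerance_mm, shell_width_mm, min_fraction)
        return cls(
            residuals=residuals,
            reliable_radius_mm=radius,
            tolerance_mm=tolerance_mm,
            shell_width_mm=shell_width_mm,
            shells=shells,
            provenance=provenance or {},
        )

    def to_json(self, path=None) -> str:
        payload = {
            "reliable_radius_mm": self.reliable_radius_mm,
            "tolerance_mm": self.tolerance_mm,
            "shell_width_mm": self.shell_width_mm,
            "shells": self.shells.to_dict(orient="records"),
            "n_markers": len(self.residuals),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text + "\n")
        return text

    def to_csv(self, path) -> pathlib.Path:
        return self.residuals.to_csv(path)


def default_tolerance(voxel_spacing) -> float:
    """Half the voxel diagonal: below this, residuals are indistinguishable
    from interpolation noise."""
    return 0.5 * float(np.linalg.norm(voxel_spacing))
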