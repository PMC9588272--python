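"""Marker detection, deformation-field sampling and distortion statistics.

The deformation field produced by registration is dense, but only marker
positions carry trustworthy displacement estimates (the phantom interior
is uniform).  This module thresholds the MR image into a marker mask,
extracts per-marker intensity-weighted centroids, samples the field at the
corresponding CT-space centroids, and summarises distortion magnitude as a
function of 3D distance from scanner isocenter, in the standard annuli
0-100 mm, 100-200 mm and > 200 mm.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import sample_field
from .volume import DeformationField, ImageVolume

__all__ = [
    "Marker",
    "MarkerSet",
    "DistortionReport",
    "ConstancyVerdict",
    "marker_mask",
    "extract_markers",
    "compute_distortion",
    "summarize",
    "compare_to_baseline",
    "match_to_ground_truth",
]

MARKER_COLUMNS = [
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


# ------------------------------------------------------------- detection

def marker_mask(
    mr: ImageVolume,
    threshold_strategy: str = "otsu",
    threshold: float | None = None,
    percentile: float | None = None,
    opening_radius: int = 1,
) -> np.ndarray:
    """Binary marker mask from MR intensity.

    Strategies: ``otsu`` (default, bimodal marker/body histogram),
    ``fixed`` (explicit ``threshold``), ``percentile`` (of the intensity
    distribution).  A morphological opening of ``opening_radius`` voxels
    removes speckle.  Pathological thresholds — an empty mask, or one
    covering more than half of the phantom body — raise ``ValueError``.
    """
    data = np.asarray(mr.data, dtype=float)
    if threshold_strategy == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(data))
    elif threshold_strategy == "fixed":
        if threshold is None:
            raise ValueError("fixed strategy requires threshold=")
        thr = float(threshold)
    elif threshold_strategy == "percentile":
        if percentile is None:
            raise ValueError("percentile strategy requires percentile=")
        thr = float(np.percentile(data, percentile))
    else:
        raise ValueError(f"unknown threshold strategy {threshold_strategy!r}")

    mask = data > thr
    if opening_radius > 0 and mask.any():
        struct = ndimage.generate_binary_structure(3, 1)
        struct = ndimage.iterate_structure(struct, opening_radius)
        mask = ndimage.binary_opening(mask, structure=struct)
    if not mask.any():
        raise ValueError(f"marker mask is empty (threshold {thr:.4g})")
    body = data > (float(data.min()) + 1e-9)
    if body.any() and mask.sum() > 0.5 * body.sum():
        raise ValueError(
            f"marker mask covers {mask.sum() / body.sum():.0%} of the body; "
            f"threshold {thr:.4g} is pathological"
        )
    return mask


def extract_markers(
    mask: np.ndarray,
    intensity: ImageVolume,
    min_voxels: int | None = None,
) -> np.ndarray:
    """Per-marker intensity-weighted centroids in world mm, (N, 3).

    26-connected component labelling; components smaller than
    ``min_voxels`` (pass half the expected marker voxel volume when the
    phantom geometry is known) are discarded; components more than three
    times the median size are flagged with a warning, the signature of two
    markers merged by a dilated mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("marker mask is empty")
    struct = np.ones((3, 3, 3), bool)  # 26-connectivity
    labels, n = ndimage.label(mask, structure=struct)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.where(sizes >= (min_voxels if min_voxels is not None else 1))[0] + 1
    if len(keep) == 0:
        raise ValueError("no marker component survives the minimum-size filter")
    med = float(np.median(sizes[keep - 1]))
    big = sizes[keep - 1] > 3.0 * med
    if np.any(big):
        warnings.warn(
            f"{int(big.sum())} marker component(s) exceed 3x the median size "
            "(possible merged markers)",
            stacklevel=2,
        )
    weights = np.asarray(intensity.data, dtype=float) * mask
    coms = ndimage.center_of_mass(weights, labels, index=keep)
    return np.atleast_2d(intensity.index_to_world(np.asarray(coms, dtype=float)))


# ------------------------------------------------------------- containers

@dataclass
class Marker:
    centroid: np.ndarray  # world mm
    vector: np.ndarray  # distortion, mm
    magnitude: float
    radial_distance: float


@dataclass
class MarkerSet:
    """Per-marker distortion table plus provenance."""

    table: pd.DataFrame
    isocenter: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        missing = set(MARKER_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"marker table is missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> list[Marker]:
        return [
            Marker(
                centroid=row[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                vector=row[["ux_mm", "uy_mm", "uz_mm"]].to_numpy(dtype=float),
                magnitude=float(row["magnitude_mm"]),
                radial_distance=float(row["r_mm"]),
            )
            for _, row in self.table.iterrows()
        ]

    def to_csv(self, path) -> pathlib.Path:
        path = pathlib.Path(path)
        self.table.to_csv(path, index=False, float_format="%.6f")
        return path

    @classmethod
    def from_csv(cls, path, isocenter=(0.0, 0.0, 0.0)) -> "MarkerSet":
        return cls(table=pd.read_csv(path), isocenter=np.asarray(isocenter, float))


def compute_distortion(
    field: DeformationField,
    centroids: np.ndarray,
    isocenter=None,
    min_separation: float | None = None,
    provenance: dict | None = None,
) -> MarkerSet:
    """Sample the deformation field at CT-space marker centroids.

    The distortion vector of a marker is the field at its CT centroid (the
    fixed grid is the geometry reference); magnitude is the Euclidean norm
    and radial distance is the 3D distance from the isocenter (defaults to
    the field volume's geometric center).
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(centroids) == 0:
        raise ValueError("no marker centroids supplied")
    iso = field.center_world if isocenter is None else np.asarray(isocenter, dtype=float)
    if min_separation is not None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centroids).query(centroids, k=2)
        if len(centroids) > 1 and np.any(d[:, 1] < min_separation):
            raise ValueError("marker centroids closer than the minimum separation")
    vec = sample_field(field, centroids)
    table = pd.DataFrame(
        {
            "marker_id": np.arange(len(centroids)),
            "x_mm": centroids[:, 0],
            "y_mm": centroids[:, 1],
            "z_mm": centroids[:, 2],
            "ux_mm": vec[:, 0],
            "uy_mm": vec[:, 1],
            "uz_mm": vec[:, 2],
            "magnitude_mm": np.linalg.norm(vec, axis=1),
            "r_mm": np.linalg.norm(centroids - iso, axis=1),
        }
    )
    return MarkerSet(table=table, isocenter=iso, provenance=provenance or {})


# ------------------------------------------------------------- statistics

def _stats(mags: np.ndarray) -> dict:
    if len(mags) == 0:
        return dict(n=0, median_mm=None, q95_mm=None, max_mm=None, mean_mm=None)
    return dict(
        n=int(len(mags)),
        median_mm=float(np.median(mags)),
        # linear interpolation between order statistics (numpy default rule)
        q95_mm=float(np.quantile(mags, 0.95)),
        max_mm=float(np.max(mags)),
        mean_mm=float(np.mean(mags)),
    )


@dataclass
class DistortionReport:
    """Binned distortion summary.

    ``bins`` are disjoint half-open annuli ``[lo, hi)`` of radial distance
    (a marker at exactly 100 mm falls in the 100-200 mm bin);
    ``cumulative`` holds within-R statistics over all markers with
    ``r <= R``.  Histogram counts use fixed-width magnitude bins.
    """

    bin_edges: tuple
    bins: list
    cumulative: dict
    histogram: dict
    n_markers: int
    isocenter: list
    provenance: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bin_edges_mm": list(self.bin_edges),
            "bins": self.bins,
            "cumulative_within_mm": self.cumulative,
            "histogram": self.histogram,
            "n_markers": self.n_markers,
            "isocenter_mm": list(self.isocenter),
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "DistortionReport":
        if isinstance(source, (str, pathlib.Path)) and pathlib.Path(str(source)).exists():
            payload = json.loads(pathlib.Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            bin_edges=tuple(payload["bin_edges_mm"]),
            bins=payload["bins"],
            cumulative={float(k): v for k, v in payload["cumulative_within_mm"].items()},
            histogram=payload["histogram"],
            n_markers=payload["n_markers"],
            isocenter=payload["isocenter_mm"],
            provenance=payload.get("provenance", {}),
        )

    def to_text(self) -> str:
        lines = ["Geometric distortion summary (mm, distances from isocenter)", ""]
        lines.append(f"{'region':>14} {'n':>5} {'median':>8} {'q95':>8} {'max':>8} {'mean':>8}")
        for b in self.bins:
            label = f"{b['lo_mm']:.0f}-{b['hi_mm']:.0f} mm" if np.isfinite(b["hi_mm"]) else f"> {b['lo_mm']:.0f} mm"
            if b["n"]:
                lines.append(
                    f"{label:>14} {b['n']:>5} {b['median_mm']:>8.3f} {b['q95_mm']:>8.3f} "
                    f"{b['max_mm']:>8.3f} {b['mean_mm']:>8.3f}"
                )
            else:
                lines.append(f"{label:>14} {0:>5} {'-':>8} {'-':>8} {'-':>8} {'-':>8}")
        for r, s in self.cumulative.items():
            if s["n"]:
                lines.append(
                    f"{'r <= ' + str(r) + ' mm':>14} {s['n']:>5} {s['median_mm']:>8.3f} "
                    f"{s['q95_mm']:>8.3f} {s['max_mm']:>8.3f} {s['mean_mm']:>8.3f}"
                )
        lines.append("")
        lines.append(f"total markers: {self.n_markers}")
        return "\n".join(lines)


def summarize(
    markers: MarkerSet,
    bin_edges: tuple = (100.0, 200.0),
    cumulative_radii: tuple = (150.0,),
    hist_bin_width: float = 0.25,
) -> DistortionReport:
    """Per-annulus and cumulative within-R statistics of distortion magnitude."""
    if len(markers) == 0:
        raise ValueError("cannot summarise an empty marker set")
    mags = markers.table["magnitude_mm"].to_numpy(dtype=float)
    r = markers.table["r_mm"].to_numpy(dtype=float)

    edges = [0.0, *sorted(float(e) for e in bin_edges), np.inf]
    bins = []
    hist = {"bin_width_mm": float(hist_bin_width), "annuli": []}
    n_hist = int(np.ceil(max(mags.max() / hist_bin_width, 1.0)))
    hist_edges = np.arange(n_hist + 1) * hist_bin_width
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (r >= lo) & (r < hi)
        bins.append(dict(lo_mm=float(lo), hi_mm=float(hi), **_stats(mags[sel])))
        counts, _ = np.histogram(mags[sel], bins=hist_edges)
        hist["annuli"].append(
            dict(lo_mm=float(lo), hi_mm=float(hi), counts=[int(c) for c in counts])
        )
    hist["magnitude_edges_mm"] = [float(e) for e in hist_edges]

    cumulative = {float(R): _stats(mags[r <= R]) for R in cumulative_radii}
    assert sum(b["n"] for b in bins) == len(mags)
    return DistortionReport(
        bin_edges=tuple(float(e) for e in bin_edges),
        bins=bins,
        cumulative=cumulative,
        histogram=hist,
        n_markers=int(len(mags)),
        isocenter=[float(v) for v in markers.isocenter],
        provenance=dict(markers.provenance),
    )


# ------------------------------------------------------------- constancy

_COMPARED_STATS = ("median_mm", "q95_mm", "max_mm", "mean_mm")


@dataclass
class ConstancyVerdict:
    passed: bool
    details: list  # per bin/statistic: delta and verdict

    def to_dict(self) -> dict:
        return {"passed": self.passed, "details": self.details}


def compare_to_baseline(
    current: DistortionReport,
    baseline: DistortionReport,
    tolerances: dict | float = 0.5,
) -> ConstancyVerdict:
    """Constancy check of a QA run against its baseline.

    Each per-bin statistic is compared by absolute difference against the
    tolerance (a scalar applies to every statistic; a dict keyed by
    statistic name overrides individually, in mm).  Overall pass iff every
    compared statistic passes.
    """
    if np.isscalar(tolerances):
        tolerances = {s: float(tolerances) for s in _COMPARED_STATS}
    if tuple(current.bin_edges) != tuple(baseline.bin_edges):
        raise ValueError("current and baseline reports use different radial bins")
    details = []
    passed = True
    for cur, base in zip(current.bins, baseline.bins):
        for stat in _COMPARED_STATS:
            if stat not in tolerances:
                continue
            c, b = cur.get(stat), base.get(stat)
            if c is None or b is None:
                continue
            delta = abs(c - b)
            ok = bool(delta <= tolerances[stat])
            passed &= ok
            details.append(
                dict(
                    bin=f"{cur['lo_mm']:.0f}-{cur['hi_mm']:.0f}",
                    statistic=stat,
                    current=c,
                    baseline=b,
                    delta=delta,
                    tolerance=tolerances[stat],
                    passed=ok,
                )
            )
    return ConstancyVerdict(passed=bool(passed), details=details)


# ------------------------------------------------------------- test helper

def match_to_ground_truth(
    centroids: np.ndarray, truth_positions: np.ndarray, gate_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour matching of detected centroids to ground-truth
    positions with a distance gate; returns (centroid_idx, truth_idx) of
    matched pairs.  Unmatched markers are reported via a warning, never
    silently dropped."""
    from scipy.spatial import cKDTree

    tree = cKDTree(np.atleast_2d(truth_positions))
    d, j = tree.query(np.atleast_2d(centroids))
    ok = d <= gate_mm
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} detected marker(s) unmatched within {gate_mm} mm", stacklevel=2)
    return np.where(ok)[0], j[ok]
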