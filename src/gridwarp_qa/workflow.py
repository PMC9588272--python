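"""End-to-end QA workflow: convert -> crop/mask -> register -> analyze ->
validate -> report, driven by a single serialisable configuration.

Every intermediate artefact is written to the run directory and linked in
a machine-readable manifest; each report embeds the configuration hash so
baselines are only compared between runs with matching settings.  For a
fixed configuration (and seed, when simulating) the whole run is
deterministic: repeated runs produce bit-identical reports.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import io as gio
from .analysis import (
    DistortionReport,
    MarkerSet,
    compare_to_baseline,
    compute_distortion,
    extract_markers,
    marker_mask,
    summarize,
)
from .registration import RegistrationConfig, apply_deformation, bspline_register
from .residual import ResidualReport, default_tolerance, residual_markers, residual_register
from .synthetic import DistortionModel, PhantomSpec, build_phantom_ct, build_phantom_mr
from .volume import ImageVolume

logger = logging.getLogger("gridwarp_qa")

__all__ = ["RunConfig", "run_workflow", "make_figures", "WorkflowError"]


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


_DEFAULT_CONFIG = {
    "inputs": {
        # either explicit files ...
        "ct": None,  # NIfTI path or DICOM directory
        "mr": None,
        # ... or a synthetic pair
        "simulate": None,  # {"phantom": {...}, "model": {...}, "shape", "spacing", "noise_sigma"}
    },
    "crop": None,  # "x0:x1,y0:y1,z0:z1" applied to both volumes
    "mask_housing": None,  # {"strategy": ..., "band"/"body_threshold"/"erosion_mm": ...}
    "registration": {
        "control_point_spacing": None,
        "pyramid_levels": 3,
        "similarity": "ssd",
        "max_iterations": 100,
        "convergence_tolerance": 1e-6,
        "bending_energy_weight": 1e-3,
        "backend": "builtin",
    },
    "analysis": {
        "isocenter": None,  # world mm; null = volume center
        "bin_edges": [100.0, 200.0],
        "cumulative_radii": [150.0],
        "marker_threshold": "otsu",
        "min_voxels": None,
    },
    "residual": {
        "enabled": True,
        "tolerance_mm": None,  # null = half the voxel diagonal
        "shell_width_mm": 10.0,
        "min_fraction": 0.95,
    },
    "baseline": None,  # {"report": path, "tolerances": float | {stat: mm}}
    "seed": 0,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """All stage parameters of a QA run, round-trippable through YAML.

    The hash is computed over the canonical (key-sorted) JSON rendering,
    so it is stable under key reordering in the source file.
    """

    settings: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.settings = _merge(_DEFAULT_CONFIG, self.settings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(settings=yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.settings, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @property
    def hash(self) -> str:
        canon = json.dumps(self.settings, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def registration_config(self) -> RegistrationConfig:
        return RegistrationConfig(**self.settings["registration"])


def _load_volume(source) -> ImageVolume:
    p = pathlib.Path(str(source))
    if p.is_dir():
        return gio.read_dicom_series(p)
    return gio.read_nifti(p)


def _stage(manifest, name, outputs, t0):
    manifest["stages"].append(
        {"stage": name, "outputs": [str(o) for o in outputs], "seconds": round(time.time() - t0, 3)}
    )
    logger.info("stage %-12s done in %.2fs", name, time.time() - t0)


def run_workflow(config: RunConfig, out_dir) -> tuple[DistortionReport, ResidualReport | None, dict]:
    """Execute the full QA workflow; returns (distortion report, residual
    report, manifest).  Any stage failure raises :class:`WorkflowError`
    naming the stage; artefacts written before the failure are retained."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.settings
    manifest = {"config_hash": config.hash, "stages": []}
    config.to_yaml(out / "config.yaml")

    # ---- stage: inputs (convert / simulate)
    t0 = time.time()
    try:
        sim = cfg["inputs"].get("simulate")
        if sim is not None:
            spec = PhantomSpec(**sim.get("phantom", {}))
            model = DistortionModel(**sim.get("model", {}))
            shape = tuple(sim.get("shape", (96, 96, 96)))
            spacing = sim.get("spacing", 4.0)
            noise = float(sim.get("noise_sigma", 0.0))
            ct = build_phantom_ct(spec, shape=shape, spacing=spacing)
            mr = build_phantom_mr(
                spec, model, shape=shape, spacing=spacing, noise_sigma=noise, seed=int(cfg["seed"])
            )
        else:
            if not cfg["inputs"].get("ct") or not cfg["inputs"].get("mr"):
                raise ValueError("inputs require either 'simulate' or both 'ct' and 'mr'")
            ct = _load_volume(cfg["inputs"]["ct"])
            mr = _load_volume(cfg["inputs"]["mr"])
        ct_path = gio.write_nifti(ct, out / "ct.nii.gz")
        mr_path = gio.write_nifti(mr, out / "mr.nii.gz")
    except Exception as e:  # noqa: BLE001
        raise WorkflowError("inputs", str(e)) from e
    _stage(manifest, "inputs", [ct_path, mr_path], t0)

    # ---- stage: crop / housing mask
    t0 = time.time()
    try:
        if cfg["crop"]:
            box = gio.CropBox.parse(cfg["crop"])
            ct, mr = gio.crop(ct, box), gio.crop(mr, box)
        if cfg["mask_housing"]:
            params = dict(cfg["mask_housing"])
            strategy = params.pop("strategy", "intensity_band")
            if "band" in params and params["band"] is not None:
                params["band"] = tuple(params["band"])
            ct = gio.mask_housing(ct, strategy=strategy, **params)
        ct_prep = gio.write_nifti(ct, out / "ct_prepared.nii.gz")
    except Exception as e:  # noqa: BLE001
        raise WorkflowError("prepare", str(e)) from e
    _stage(manifest, "prepare", [ct_prep], t0)

    # ---- stage: deformable registration
    t0 = time.time()
    try:
        reg_cfg = config.registration_config()
        body_mask = ct.data > (float(np.min(ct.data)) + 1e-9)
        field = bspline_register(mr, ct, reg_cfg, fixed_mask=body_mask)
        deformed = apply_deformation(mr, field)
        field_path = gio.write_field(field, out / "field.nii.gz")
        def_path = gio.write_nifti(deformed, out / "mr_deformed.nii.gz")
    except Exception as e:  # noqa: BLE001
        raise WorkflowError("register", str(e)) from e
    _stage(manifest, "register", [field_path, def_path], t0)

    # ---- stage: distortion analysis
    t0 = time.time()
    try:
        ana = cfg["analysis"]
        mask = marker_mask(mr, threshold_strategy=ana["marker_threshold"])
        centroids = extract_markers(mask, mr, min_voxels=ana["min_voxels"])
        iso = ana["isocenter"]
        markers = compute_distortion(
            field,
            centroids,
            isocenter=None if iso is None else np.asarray(iso, float),
            provenance={"config_hash": config.hash},
        )
        report = summarize(
            markers,
            bin_edges=tuple(ana["bin_edges"]),
            cumulative_radii=tuple(ana["cumulative_radii"]),
        )
        markers_path = markers.to_csv(out / "markers.csv")
        report_json = out / "report.json"
        report.to_json(report_json)
        (out / "report.txt").write_text(report.to_text() + "\n")
        figures = make_figures(report, markers, out)
    except Exception as e:  # noqa: BLE001
        raise WorkflowError("analyze", str(e)) from e
    _stage(manifest, "analyze", [markers_path, report_json, out / "report.txt", *figures], t0)

    # ---- stage: residual validation
    residual_report = None
    if cfg["residual"]["enabled"]:
        t0 = time.time()
        try:
            res_field = residual_register(deformed, ct, reg_cfg, fixed_mask=body_mask)
            res_mk = residual_markers(
                res_field,
                centroids,
                isocenter=None if iso is None else np.asarray(iso, float),
                provenance={"config_hash": config.hash},
            )
            tol = cfg["residual"]["tolerance_mm"]
            tol = default_tolerance(ct.spacing) if tol is None else float(tol)
            residual_report = ResidualReport.from_markers(
                res_mk,
                tolerance_mm=tol,
                shell_width_mm=float(cfg["residual"]["shell_width_mm"]),
                min_fraction=float(cfg["residual"]["min_fraction"]),
                provenance={"config_hash": config.hash},
            )
            res_json = out / "residual.json"
            residual_report.to_json(res_json)
            res_csv = residual_report.to_csv(out / "residual_markers.csv")
            res_fig = _residual_figure(residual_report, out / "residual_markers.png")
        except Exception as e:  # noqa: BLE001
            raise WorkflowError("validate", str(e)) from e
        _stage(manifest, "validate", [res_json, res_csv, res_fig], t0)

    # ---- stage: constancy
    if cfg["baseline"]:
        t0 = time.time()
        try:
            baseline = DistortionReport.from_json(cfg["baseline"]["report"])
            verdict = compare_to_baseline(
                report, baseline, tolerances=cfg["baseline"].get("tolerances", 0.5)
            )
            const_path = out / "constancy.json"
            const_path.write_text(json.dumps(verdict.to_dict(), indent=2) + "\n")
        except Exception as e:  # noqa: BLE001
            raise WorkflowError("constancy", str(e)) from e
        _stage(manifest, "constancy", [const_path], t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return report, residual_report, manifest


# ------------------------------------------------------------------ figures

_ANNULUS_COLORS = ("tab:blue", "tab:green", "tab:red")


def _annulus_split(markers: MarkerSet, edges):
    r = markers.table["r_mm"].to_numpy(float)
    m = markers.table["magnitude_mm"].to_numpy(float)
    bounds = [0.0, *edges, np.inf]
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (r >= lo) & (r < hi)
        label = f"{lo:.0f}–{hi:.0f} mm" if np.isfinite(hi) else f"> {lo:.0f} mm"
        out.append((label, r[sel], m[sel]))
    return out


def make_figures(report: DistortionReport, markers: MarkerSet, out_dir) -> list[pathlib.Path]:
    """Scatter of distortion magnitude vs distance from isocenter and a
    per-annulus magnitude histogram, colour-coded blue/green/red for the
    0-100 / 100-200 / > 200 mm regions."""
    if len(markers) == 0:
        raise ValueError("cannot plot an empty marker set")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    paths = []
    split = _annulus_split(markers, report.bin_edges)

    fig, ax = plt.subplots(figsize=(6, 4))
    for (label, r, m), color in zip(split, _ANNULUS_COLORS):
        ax.scatter(r, m, s=14, c=color, label=label, alpha=0.8, edgecolors="none")
    ax.set_xlabel("3D distance from isocenter (mm)")
    ax.set_ylabel("distortion magnitude (mm)")
    ax.legend(title="region", fontsize=8)
    fig.tight_layout()
    p = out_dir / "distortion_vs_distance.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    width = report.histogram["bin_width_mm"]
    edges = np.asarray(report.histogram["magnitude_edges_mm"])
    mags = [m for _, _, m in split]
    ax.hist(
        mags,
        bins=edges,
        color=list(_ANNULUS_COLORS[: len(mags)]),
        label=[lab for lab, _, _ in split],
        stacked=True,
    )
    ax.set_xlabel(f"distortion magnitude (mm, {width} mm bins)")
    ax.set_ylabel("marker count")
    ax.legend(title="region", fontsize=8)
    fig.tight_layout()
    p = out_dir / "distortion_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths


def _residual_figure(res: ResidualReport, path) -> pathlib.Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = res.residuals.table
    bad = t["magnitude_mm"] > res.tolerance_mm
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(t.x_mm[~bad], t.y_mm[~bad], t.z_mm[~bad], c="tab:gray", s=10, alpha=0.4,
               label="residual within tolerance")
    ax.scatter(t.x_mm[bad], t.y_mm[bad], t.z_mm[bad], c="tab:red", s=18,
               label="unreliable region")
    ax.set_title(f"reliable radius {res.reliable_radius_mm:.0f} mm "
                 f"(tolerance {res.tolerance_mm:.2f} mm)")
    ax.set_xlabel("x (mm)"); ax.set_ylabel("y (mm)"); ax.set_zlabel("z (mm)")
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return pathlib.Path(path)
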