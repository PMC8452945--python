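"""Case configuration, file I/O and the end-to-end pipeline.

A *case* is two angiogram images with their acquisition geometries, vessel
endpoints (manual pixel coordinates or the skeleton heuristic), a template
centerline, and segmentation/reconstruction parameters.  ``run_pipeline``
executes segmentation on both views, template-ratio correspondence, panning
estimation, triangulation and diameter conversion, and writes the centerline
CSV, surface meshes, masks and a JSON run report.

All randomness in a run is driven by the single config seed; the numerical
stages themselves are deterministic, so a fixed config yields byte-identical
outputs.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image

from . import segmentation as seg
from .curves import Centerline2D
from .geometry import AcquisitionGeometry
from .reconstruction import export_surface, reconstruct
from .template import correspond, load_template, ratio_table

__all__ = [
    "ConfigError",
    "CaseConfig",
    "RunReport",
    "read_case_config",
    "write_report",
    "load_image",
    "save_image",
    "save_mask",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Configuration schema violation, reported with the offending field path."""


_SEG_DEFAULTS = {
    "scales": list(seg.DEFAULT_SCALES),
    "beta": seg.DEFAULT_BETA,
    "c": None,
    "threshold": seg.DEFAULT_THRESHOLD,
    "snap_radius": seg.DEFAULT_SNAP_RADIUS,
    "step_px": 1.0,
    "polarity": "dark",
}


@dataclass
class CaseConfig:
    """Validated reconstruction-case configuration."""

    image1: str
    image2: str
    geometry1: AcquisitionGeometry
    geometry2: AcquisitionGeometry
    template: str
    output_dir: str = "out"
    endpoint_mode: str = "manual"  # "manual" | "heuristic"
    endpoints1: tuple = None  # ((row, col), (row, col)) when manual
    endpoints2: tuple = None
    segmentation: dict = field(default_factory=lambda: dict(_SEG_DEFAULTS))
    fit_panning: bool = True
    artery_type: str = "LAD"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "image1": self.image1,
            "image2": self.image2,
            "geometry1": self.geometry1.to_dict(),
            "geometry2": self.geometry2.to_dict(),
            "template": self.template,
            "output_dir": self.output_dir,
            "endpoint_mode": self.endpoint_mode,
            "segmentation": dict(self.segmentation),
            "fit_panning": self.fit_panning,
            "artery_type": self.artery_type,
            "seed": self.seed,
        }
        if self.endpoints1 is not None:
            d["endpoints1"] = [[float(v) for v in p] for p in self.endpoints1]
        if self.endpoints2 is not None:
            d["endpoints2"] = [[float(v) for v in p] for p in self.endpoints2]
        return d


_TOP_KEYS = {
    "image1", "image2", "geometry1", "geometry2", "template", "output_dir",
    "endpoint_mode", "endpoints1", "endpoints2", "segmentation", "fit_panning",
    "artery_type", "seed",
}


def _parse_config_dict(raw: dict, base_dir: str = ".") -> CaseConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for req in ("image1", "image2", "geometry1", "geometry2", "template"):
        if req not in raw:
            raise ConfigError(f"missing required config key: {req}")

    def resolve(p):
        p = str(p)
        return p if os.path.isabs(p) else os.path.join(base_dir, p)

    try:
        g1 = AcquisitionGeometry.from_dict(raw["geometry1"])
        g2 = AcquisitionGeometry.from_dict(raw["geometry2"])
    except Exception as exc:
        raise ConfigError(f"geometry: {exc}") from exc

    segmentation = dict(_SEG_DEFAULTS)
    for k, v in (raw.get("segmentation") or {}).items():
        if k not in _SEG_DEFAULTS:
            raise ConfigError(f"segmentation: unknown key {k!r}")
        segmentation[k] = v

    mode = raw.get("endpoint_mode", "manual")
    if mode not in ("manual", "heuristic"):
        raise ConfigError(f"endpoint_mode: must be 'manual' or 'heuristic', got {mode!r}")
    endpoints = {}
    for key in ("endpoints1", "endpoints2"):
        if key in raw and raw[key] is not None:
            pts = raw[key]
            if len(pts) != 2 or any(len(p) != 2 for p in pts):
                raise ConfigError(f"{key}: expected [[row, col], [row, col]]")
            endpoints[key] = tuple(tuple(float(v) for v in p) for p in pts)
    if mode == "manual" and ("endpoints1" not in endpoints or "endpoints2" not in endpoints):
        raise ConfigError("endpoint_mode 'manual' requires endpoints1 and endpoints2")

    return CaseConfig(
        image1=resolve(raw["image1"]),
        image2=resolve(raw["image2"]),
        geometry1=g1,
        geometry2=g2,
        template=resolve(raw["template"]),
        output_dir=resolve(raw.get("output_dir", "out")),
        endpoint_mode=mode,
        endpoints1=endpoints.get("endpoints1"),
        endpoints2=endpoints.get("endpoints2"),
        segmentation=segmentation,
        fit_panning=bool(raw.get("fit_panning", True)),
        artery_type=str(raw.get("artery_type", "LAD")),
        seed=int(raw.get("seed", 0)),
    )


def read_case_config(path) -> CaseConfig:
    """Read and validate a YAML or JSON case configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cfg = _parse_config_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))
    for label, p in (("image1", cfg.image1), ("image2", cfg.image2), ("template", cfg.template)):
        if not os.path.exists(p):
            raise ConfigError(f"{label}: file not found: {p}")
    return cfg


def write_case_config(cfg: CaseConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Serializable record of one pipeline run."""

    adps2: dict
    panning: dict
    timings_s: dict
    warnings: list
    parameters: dict

    def to_dict(self) -> dict:
        return {
            "adps2": self.adps2,
            "panning": self.panning,
            "timings_s": self.timings_s,
            "warnings": self.warnings,
            "parameters": self.parameters,
        }


def write_report(report: RunReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_image(path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG/TIFF, normalized to [0, 1]."""
    img = Image.open(path)
    arr = np.asarray(img, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 65535).astype(np.uint16)).save(path)


def save_mask(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def _endpoints_for_view(cfg: CaseConfig, which: int, image: np.ndarray):
    manual = cfg.endpoints1 if which == 1 else cfg.endpoints2
    if cfg.endpoint_mode == "manual":
        return seg.EndpointPair(start=manual[0], end=manual[1])
    vess = seg.frangi_vesselness(
        image, scales=cfg.segmentation["scales"], beta=cfg.segmentation["beta"],
        c=cfg.segmentation["c"], polarity=cfg.segmentation["polarity"])
    rough = vess > cfg.segmentation["threshold"] * vess.max()
    return seg.heuristic_endpoints(rough)


def run_pipeline(cfg: CaseConfig):
    """Execute the full two-view reconstruction; returns (centerline, report).

    Writes to ``cfg.output_dir``: per-view mask PNGs and centerline CSVs,
    the 3D centerline CSV, STL and OBJ surface meshes, and report.json.
    Any stage failure raises with a stage-labeled message.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    timings, warnings_list = {}, []

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        return out

    img1 = stage("load-image-1", load_image, cfg.image1)
    img2 = stage("load-image-2", load_image, cfg.image2)
    for label, img, geom in (("image1", img1, cfg.geometry1), ("image2", img2, cfg.geometry2)):
        if img.shape != tuple(geom.image_size):
            raise RuntimeError(f"[config] {label} shape {img.shape} does not match "
                               f"geometry image_size {geom.image_size}")

    sp = cfg.segmentation
    ep1 = stage("endpoints-1", _endpoints_for_view, cfg, 1, img1)
    ep2 = stage("endpoints-2", _endpoints_for_view, cfg, 2, img2)
    cl1, mask1, _ = stage(
        "segment-1", seg.segment_view, img1, ep1, scales=sp["scales"], beta=sp["beta"],
        c=sp["c"], threshold=sp["threshold"], snap_radius=sp["snap_radius"],
        step_px=sp["step_px"], polarity=sp["polarity"])
    cl2, mask2, _ = stage(
        "segment-2", seg.segment_view, img2, ep2, scales=sp["scales"], beta=sp["beta"],
        c=sp["c"], threshold=sp["threshold"], snap_radius=sp["snap_radius"],
        step_px=sp["step_px"], polarity=sp["polarity"])

    tmpl = stage("template", load_template, cfg.template, cfg.artery_type)
    ratios = stage("ratio-table", ratio_table, tmpl, cfg.geometry1, cfg.geometry2)
    corr = stage("correspondence", correspond, ratios, cl1, cl2)
    cl3d, adps2, panning = stage(
        "reconstruct", reconstruct, corr, cfg.geometry1, cfg.geometry2,
        fit_panning=cfg.fit_panning)
    if panning.at_bound:
        warnings_list.append("panning estimate hit the plausibility bound")

    mesh = stage("mesh", export_surface, cl3d)
    out = cfg.output_dir
    save_mask(mask1, os.path.join(out, "mask1.png"))
    save_mask(mask2, os.path.join(out, "mask2.png"))
    cl1.to_csv(os.path.join(out, "centerline_view1.csv"))
    cl2.to_csv(os.path.join(out, "centerline_view2.csv"))
    cl3d.to_csv(os.path.join(out, "centerline3d.csv"))
    mesh.export(os.path.join(out, "surface.stl"))
    mesh.export(os.path.join(out, "surface.obj"))

    report = RunReport(
        adps2=adps2.to_dict(),
        panning={"tx_mm": panning.tx, "tz_mm": panning.tz,
                 "residual_rms_px": panning.residual_rms_px,
                 "fitted": cfg.fit_panning},
        timings_s=timings,
        warnings=warnings_list,
        parameters={
            "segmentation": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                             for k, v in sp.items()},
            "geometry1": cfg.geometry1.to_dict(),
            "geometry2": cfg.geometry2.to_dict(),
            "endpoint_mode": cfg.endpoint_mode,
            "fit_panning": cfg.fit_panning,
            "artery_type": cfg.artery_type,
            "template": os.path.basename(cfg.template),
            "seed": cfg.seed,
        },
    )
    write_report(report, os.path.join(out, "report.json"))
    return cl3d, report
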