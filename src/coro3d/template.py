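"""Template-model correspondence between two segmented 2D centerlines.

Epipolar matching alone is ambiguous for foreshortened or overlapping
vessels, so point correspondence between the two views is established from a
population *template*: an averaged 3D centerline of the artery type (LAD,
LCX or RCA).  Each source model is rescaled to unit arc length, translated so
its start point sits at the origin, and resampled to n equidistant points;
the template is the coordinate-wise mean.  Viewing the template from the two
acquisition angles gives, for every template point, the fraction of projected
2D arc length from the start — and those two fraction tables pick the
matching points on the two segmented centerlines.

The template is projected orthographically (parallel rays along the view
axis): an unscaled, unplaced template has no defined perspective pose, and
arc-length *ratios* are invariant to the overall magnification anyway.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .curves import (
    Centerline2D,
    Centerline3D,
    arc_lengths,
    interp_along,
    point_at_fraction,
)
from .geometry import AcquisitionGeometry, detector_axes

__all__ = [
    "TemplateModel",
    "RatioTable",
    "CorrespondenceMap",
    "build_template",
    "template_spread",
    "ratio_table",
    "correspond",
    "save_template",
    "load_template",
    "load_model_library",
]

DEFAULT_N_POINTS = 100


@dataclass
class TemplateModel:
    """Length-normalized, start-aligned averaged centerline of one artery type.

    ``points`` has unit total arc length, starts at the origin, and its n
    points are equidistant in arc length.
    """

    points: np.ndarray
    artery_type: str = "LAD"
    n_source_models: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        cum = arc_lengths(self.points)
        if abs(cum[-1] - 1.0) > 1e-9:
            raise ValueError("template must have unit total arc length")
        if np.linalg.norm(self.points[0]) > 1e-9:
            raise ValueError("template must start at the origin")
        seg = np.diff(cum)
        if np.any(np.abs(seg - seg.mean()) > 1e-6 * seg.mean()):
            raise ValueError("template points must be equidistant in arc length")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class RatioTable:
    """Per-template-point projected arc-length fractions in the two views."""

    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self):
        for name in ("r1", "r2"):
            r = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, r)
            if abs(r[0]) > 1e-12 or abs(r[-1] - 1.0) > 1e-12:
                raise ValueError(f"{name} must run from 0 to 1")
            if np.any(np.diff(r) < -1e-12):
                raise ValueError(f"{name} must be non-decreasing")


@dataclass
class CorrespondenceMap:
    """Matched point pairs on the two 2D centerlines, proximal to distal."""

    points1: np.ndarray  # (n, 2) pixel coords on view 1
    points2: np.ndarray  # (n, 2) pixel coords on view 2
    diameters1_px: np.ndarray = None
    diameters2_px: np.ndarray = None

    def __len__(self):
        return len(self.points1)


def _chordal_walk(points: np.ndarray, chord: float, n_steps: int):
    """Place up to ``n_steps`` points each at chord distance ``chord`` along
    the polyline (first sphere-polyline crossing ahead of the current
    position).  Returns the placed points and the final arc position."""
    cum = arc_lengths(points)
    placed = [points[0]]
    seg = 0
    u_cur = 0.0
    p = points[0]
    t_cur = 0.0
    m = len(points) - 1
    for _ in range(n_steps):
        found = False
        s, u_min = seg, u_cur
        while s < m:
            a, b = points[s], points[s + 1]
            ab = b - a
            aa = float(ab @ ab)
            if aa > 0:
                ap = a - p
                bq = 2.0 * float(ap @ ab)
                cq = float(ap @ ap) - chord * chord
                disc = bq * bq - 4 * aa * cq
                if disc >= 0:
                    sq = np.sqrt(disc)
                    for u in ((-bq - sq) / (2 * aa), (-bq + sq) / (2 * aa)):
                        if u_min < u <= 1.0:
                            p = a + u * ab
                            t_cur = cum[s] + u * (cum[s + 1] - cum[s])
                            seg, u_cur = s, u
                            placed.append(p)
                            found = True
                            break
            if found:
                break
            s += 1
            u_min = 0.0
        if not found:
            # ran off the end: report overshoot proportional to leftover chord
            return np.array(placed), cum[-1] + chord - float(np.linalg.norm(points[-1] - p))
    return np.array(placed), t_cur


def _equal_chord_resample(points: np.ndarray, n: int, tol: float = 0.0,
                          max_iter: int = 100) -> np.ndarray:
    """n points on the polyline whose consecutive chord lengths are equal.

    Plain uniform-arc-length resampling leaves chord lengths varying with
    local curvature (chords cut corners).  Here the n-1 equal chords are
    found by a shooting method: walk the polyline placing points at a trial
    chord length, and bisect that length until the walk ends exactly at the
    polyline's end point.  Robust for arbitrarily jagged polylines because
    the final arc position is monotone in the chord length.
    """
    points = np.asarray(points, dtype=float)
    total = arc_lengths(points)[-1]
    lo = float(np.linalg.norm(points[-1] - points[0])) / (n - 1) * 1e-3
    hi = total / (n - 1)  # arc consumed per chord >= chord: reaches the end
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        placed, t_end = _chordal_walk(points, mid, n - 1)
        if len(placed) == n and t_end < total:
            lo = mid  # chord too short: walk stops before the end
        else:
            hi = mid  # reached or overshot the end
        if (hi - lo) <= tol * total:
            break
    placed, _ = _chordal_walk(points, lo, n - 1)
    if len(placed) < n:
        placed = np.vstack([placed] + [points[-1]] * (n - len(placed)))
    out = placed[:n].copy()
    out[-1] = points[-1]  # land exactly on the end point
    seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
    if seg.min() <= 0 or (seg.max() - seg.min()) > 1e-7 * seg.mean():
        raise ValueError(
            "cannot place equidistant points: the polyline is too jagged "
            "(arc length dominated by point-to-point noise); smooth the model first")
    return out


def _normalize_model(points: np.ndarray, n: int) -> np.ndarray:
    """Unit arc length, start at origin, n equal-arc-spaced points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("model needs at least 2 points")
    if arc_lengths(pts)[-1] <= 0:
        raise ValueError("model has zero centerline length")
    pts = _equal_chord_resample(pts, n)
    return (pts - pts[0]) / arc_lengths(pts)[-1]


def build_template(models, n: int = DEFAULT_N_POINTS, artery_type: str = "LAD") -> TemplateModel:
    """Average >= 2 centerline models into a template.

    Each model is uniformly scaled to unit arc length, translated so its
    start point is the origin, and resampled to ``n`` equidistant points;
    template point i is the coordinate-wise mean of the models' points i.
    The mean is then renormalized so the template again satisfies the
    unit-length / equidistant invariants.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to build a template")
    arrays = []
    for m in models:
        pts = m.points if isinstance(m, Centerline3D) else np.asarray(m, dtype=float)
        arrays.append(_normalize_model(pts, n))
    mean = np.mean(arrays, axis=0)
    return TemplateModel(points=_normalize_model(mean, n), artery_type=artery_type,
                         n_source_models=len(models))


def template_spread(models, template: TemplateModel):
    """Mean and SD distance from the template to the models, per arc position.

    Models are normalized exactly as in :func:`build_template` (unit length,
    start-aligned, resampled to the template's point count), so the reported
    profile is on the unit-length scale and is zero at the start point by
    construction.

    Returns
    -------
    (mean, sd) : two (n,) arrays
    """
    arrays = np.stack([_normalize_model(
        m.points if isinstance(m, Centerline3D) else m, template.n) for m in models])
    d = np.linalg.norm(arrays - template.points[None], axis=2)  # (n_models, n)
    return d.mean(axis=0), d.std(axis=0)


def _orthographic_ratios(points: np.ndarray, geom: AcquisitionGeometry) -> np.ndarray:
    u, v, _ = detector_axes(geom)
    proj = np.column_stack([points @ u, points @ v])
    cum = arc_lengths(proj)
    if cum[-1] < 1e-9:
        raise ValueError("degenerate projection: template is parallel to the view axis")
    return cum / cum[-1]


def ratio_table(template: TemplateModel, geom1: AcquisitionGeometry,
                geom2: AcquisitionGeometry) -> RatioTable:
    """Projected arc-length fraction of every template point in both views.

    The template is projected orthographically along each view axis onto the
    detector plane; r_k[i] is the cumulative projected polyline length up to
    point i divided by the total projected length in view k.
    """
    return RatioTable(
        r1=_orthographic_ratios(template.points, geom1),
        r2=_orthographic_ratios(template.points, geom2),
    )


def correspond(ratios: RatioTable, cl1: Centerline2D, cl2: Centerline2D) -> CorrespondenceMap:
    """Matched point pairs at the template's arc-length fractions.

    Pair i is (point at fraction r1[i] of centerline 1, point at fraction
    r2[i] of centerline 2), positions and diameters linearly interpolated
    along each polyline.
    """
    if len(cl1) < 2 or len(cl2) < 2:
        raise ValueError("both centerlines need at least 2 points")
    p1 = point_at_fraction(cl1.points, ratios.r1)
    p2 = point_at_fraction(cl2.points, ratios.r2)
    d1 = d2 = None
    if cl1.diameters_px is not None:
        d1 = interp_along(cl1.points, cl1.diameters_px, ratios.r1 * cl1.length)
    if cl2.diameters_px is not None:
        d2 = interp_along(cl2.points, cl2.diameters_px, ratios.r2 * cl2.length)
    return CorrespondenceMap(points1=p1, points2=p2, diameters1_px=d1, diameters2_px=d2)


def save_template(template: TemplateModel, path) -> None:
    """Write a template as CSV: index,x,y,z,arc_fraction."""
    frac = arc_lengths(template.points)
    with open(path, "w") as fh:
        fh.write("index,x,y,z,arc_fraction\n")
        for i, ((x, y, z), f) in enumerate(zip(template.points, frac)):
            fh.write(f"{i},{x:.12g},{y:.12g},{z:.12g},{f:.12g}\n")


def load_template(path, artery_type: str = "LAD") -> TemplateModel:
    data = np.atleast_1d(np.genfromtxt(path, delimiter=",", names=True))
    pts = np.column_stack([data["x"], data["y"], data["z"]])
    return TemplateModel(points=_normalize_model(pts, len(pts)), artery_type=artery_type)


def load_model_library(directory) -> list:
    """Read all model CSVs (columns x_mm,y_mm,z_mm) from a directory."""
    models = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".csv"):
            continue
        data = np.atleast_1d(np.genfromtxt(os.path.join(directory, name),
                                           delimiter=",", names=True))
        models.append(np.column_stack([data["x_mm"], data["y_mm"], data["z_mm"]]))
    if not models:
        raise FileNotFoundError(f"no model CSVs found in {directory}")
    return models
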