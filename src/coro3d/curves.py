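"""Polyline arc-length utilities and centerline containers.

Centerlines are ordered polylines: 2D ones live in detector pixel coordinates
(row, col) with per-point diameters in pixels; 3D ones live in world
millimetres with per-point lumen radii.  All resampling here is uniform in
arc length with linear interpolation between vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "arc_lengths",
    "resample_polyline",
    "resample_polyline_step",
    "interp_along",
    "point_at_fraction",
    "polyline_point_distances",
    "Centerline2D",
    "Centerline3D",
]


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline; ``out[0] = 0``."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample to ``n`` points uniformly spaced in arc length."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("polyline needs at least 2 points")
    cum = arc_lengths(points)
    if cum[-1] <= 0:
        raise ValueError("polyline has zero length")
    target = np.linspace(0.0, cum[-1], n)
    return np.column_stack([np.interp(target, cum, points[:, k]) for k in range(points.shape[1])])


def resample_polyline_step(points: np.ndarray, step: float) -> np.ndarray:
    """Resample at (approximately) uniform ``step`` arc-length spacing."""
    cum = arc_lengths(points)
    n = max(2, int(round(cum[-1] / step)) + 1)
    return resample_polyline(points, n)


def interp_along(points: np.ndarray, values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Linearly interpolate per-point ``values`` at arc-length positions ``targets``."""
    cum = arc_lengths(points)
    return np.interp(targets, cum, values)


def point_at_fraction(points: np.ndarray, frac) -> np.ndarray:
    """Point(s) at arc-length fraction(s) ``frac`` in [0, 1] of the polyline."""
    points = np.asarray(points, dtype=float)
    cum = arc_lengths(points)
    target = np.atleast_1d(np.asarray(frac, dtype=float)) * cum[-1]
    out = np.column_stack([np.interp(target, cum, points[:, k]) for k in range(points.shape[1])])
    return out[0] if np.isscalar(frac) or np.asarray(frac).ndim == 0 else out


def polyline_point_distances(query: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each query point to a polyline (nearest point on any segment)."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    poly = np.asarray(poly, dtype=float)
    a = poly[:-1]  # (m, d)
    ab = poly[1:] - a  # (m, d)
    denom = np.einsum("md,md->m", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    # t of the perpendicular foot of each query on each segment, clipped
    ap = query[:, None, :] - a[None, :, :]  # (n, m, d)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    foot = a[None] + t[..., None] * ab[None]
    return np.linalg.norm(query[:, None, :] - foot, axis=2).min(axis=1)


@dataclass
class Centerline2D:
    """Ordered proximal-to-distal centerline in pixel coordinates.

    Attributes
    ----------
    points : (n, 2) array
        Continuous ``(row, col)`` coordinates.
    diameters_px : (n,) array or None
        Per-point vessel diameter in pixels (filled by diameter measurement).
    """

    points: np.ndarray
    diameters_px: np.ndarray = None
    flagged: np.ndarray = None  # points whose diameter was interpolated

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("Centerline2D points must be (n, 2)")
        cum = arc_lengths(self.points)
        if np.any(np.diff(cum) <= 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.diameters_px is not None:
            self.diameters_px = np.asarray(self.diameters_px, dtype=float)

    @property
    def cum_length(self) -> np.ndarray:
        return arc_lengths(self.points)

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def __len__(self):
        return len(self.points)

    def to_csv(self, path) -> None:
        d = self.diameters_px if self.diameters_px is not None else np.full(len(self), np.nan)
        cum = self.cum_length
        with open(path, "w") as fh:
            fh.write("index,row,col,cum_length_px,diameter_px\n")
            for i, ((r, c), s, dd) in enumerate(zip(self.points, cum, d)):
                fh.write(f"{i},{r:.9g},{c:.9g},{s:.9g},{dd:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "Centerline2D":
        data = np.genfromtxt(path, delimiter=",", names=True)
        data = np.atleast_1d(data)
        diam = data["diameter_px"]
        return cls(
            points=np.column_stack([data["row"], data["col"]]),
            diameters_px=None if np.all(np.isnan(diam)) else diam,
        )


@dataclass
class Centerline3D:
    """Ordered 3D centerline in world millimetres with per-point lumen radii."""

    points: np.ndarray
    radii_mm: np.ndarray = None
    residuals_px: np.ndarray = None  # view-2 projection distance after triangulation

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("Centerline3D points must be (n, 3)")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.radii_mm is not None:
            self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        if self.residuals_px is not None:
            self.residuals_px = np.asarray(self.residuals_px, dtype=float)

    @property
    def cum_length(self) -> np.ndarray:
        return arc_lengths(self.points)

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def __len__(self):
        return len(self.points)

    def to_csv(self, path) -> None:
        r = self.radii_mm if self.radii_mm is not None else np.full(len(self), np.nan)
        res = self.residuals_px if self.residuals_px is not None else np.full(len(self), np.nan)
        with open(path, "w") as fh:
            fh.write("index,x_mm,y_mm,z_mm,radius_mm,residual_px\n")
            for i, ((x, y, z), rr, ee) in enumerate(zip(self.points, r, res)):
                fh.write(f"{i},{x:.9g},{y:.9g},{z:.9g},{rr:.9g},{ee:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "Centerline3D":
        data = np.atleast_1d(np.genfromtxt(path, delimiter=",", names=True))
        names = data.dtype.names
        pts = np.column_stack([data["x_mm"], data["y_mm"], data["z_mm"]])
        radii = data["radius_mm"] if "radius_mm" in names else None
        if radii is not None and np.all(np.isnan(radii)):
            radii = None
        return cls(points=pts, radii_mm=radii)
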