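"""C-arm cone-beam acquisition geometry.

A single-plane angiographic view is described by the clinical gantry angles
(LAO/RAO primary rotation, CRA/CAU secondary tilt), the source-to-isocenter
distance (SOD), the source-to-detector distance (SDD) and the detector pixel
pitch.  The world frame has its origin at the isocenter with

    x = patient's left,  y = patient's anterior,  z = cranial.

The view axis (unit vector from the source toward the detector) for primary
angle ``alpha`` (LAO positive, RAO negative) and secondary angle ``beta``
(CRA positive, CAU negative) is

    d(alpha, beta) = (sin(a) cos(b),  cos(a) cos(b),  sin(b))

so the AP view (alpha = beta = 0) has the source posterior to the patient and
the detector anterior.  The X-ray source sits at ``-sod * d`` and the detector
center at ``(sdd - sod) * d``.  In-plane detector axes are chosen so that image
columns increase toward the rotated patient-left direction and image rows
increase caudally; detector roll about the central ray is fixed at zero.

Pixel coordinates are continuous ``(row, col)`` with pixel centers at integer
positions and row 0 at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "GeometryError",
    "view_direction",
    "detector_axes",
    "source_position",
    "project_point",
    "project_points",
    "backproject_ray",
]


class GeometryError(ValueError):
    """Raised for geometrically invalid inputs (e.g. point behind the source)."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """One view's C-arm pose and detector parameters.

    Parameters
    ----------
    alpha : float
        Signed primary angle in degrees; LAO positive, RAO negative.
    beta : float
        Signed secondary angle in degrees; CRA positive, CAU negative.
    sod : float
        Source-to-isocenter distance in mm.
    sdd : float
        Source-to-detector distance in mm; must exceed ``sod``.
    pixel_spacing : float
        Detector pixel pitch in mm/pixel.
    image_size : tuple of int
        ``(rows, cols)`` of the detector image.
    principal_point : tuple of float, optional
        ``(row, col)`` where the central ray meets the detector; defaults to
        the image center.
    """

    alpha: float = 0.0
    beta: float = 0.0
    sod: float = 750.0
    sdd: float = 1000.0
    pixel_spacing: float = 0.2
    image_size: tuple = (512, 512)
    principal_point: tuple = field(default=None)

    def __post_init__(self):
        if not (self.sdd > self.sod > 0):
            raise GeometryError(f"require sdd > sod > 0, got sod={self.sod}, sdd={self.sdd}")
        if self.pixel_spacing <= 0:
            raise GeometryError("pixel_spacing must be positive")
        rows, cols = self.image_size
        if rows < 2 or cols < 2:
            raise GeometryError("image_size components must be >= 2")
        if not (-180 < self.alpha <= 180):
            raise GeometryError(f"alpha out of range (-180, 180]: {self.alpha}")
        if not (-90 <= self.beta <= 90):
            raise GeometryError(f"beta out of range [-90, 90]: {self.beta}")
        if self.principal_point is None:
            object.__setattr__(
                self, "principal_point", ((rows - 1) / 2.0, (cols - 1) / 2.0)
            )

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        """Build from the config keys alpha_deg/beta_deg/sod_mm/sdd_mm/... ."""
        kwargs = {}
        mapping = {
            "alpha_deg": "alpha",
            "beta_deg": "beta",
            "sod_mm": "sod",
            "sdd_mm": "sdd",
            "pixel_spacing_mm": "pixel_spacing",
        }
        for key, attr in mapping.items():
            if key in d:
                kwargs[attr] = float(d[key])
        if "rows" in d or "cols" in d:
            kwargs["image_size"] = (int(d.get("rows", 512)), int(d.get("cols", 512)))
        if "principal_point" in d and d["principal_point"] is not None:
            kwargs["principal_point"] = tuple(float(v) for v in d["principal_point"])
        known = set(mapping) | {"rows", "cols", "principal_point"}
        unknown = set(d) - known
        if unknown:
            raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha_deg": float(self.alpha),
            "beta_deg": float(self.beta),
            "sod_mm": float(self.sod),
            "sdd_mm": float(self.sdd),
            "pixel_spacing_mm": float(self.pixel_spacing),
            "rows": int(self.image_size[0]),
            "cols": int(self.image_size[1]),
            "principal_point": [float(v) for v in self.principal_point],
        }


def view_direction(geom: AcquisitionGeometry) -> np.ndarray:
    """Unit vector along the central ray, from source toward detector."""
    a = np.deg2rad(geom.alpha)
    b = np.deg2rad(geom.beta)
    return np.array([np.sin(a) * np.cos(b), np.cos(a) * np.cos(b), np.sin(b)])


def detector_axes(geom: AcquisitionGeometry):
    """In-plane detector axes ``(u, v)`` and the view axis ``d``.

    ``u`` points along increasing image columns, ``v`` along increasing image
    rows (caudally for beta = 0); ``(u, v, d)`` is orthonormal.
    """
    a = np.deg2rad(geom.alpha)
    b = np.deg2rad(geom.beta)
    d = np.array([np.sin(a) * np.cos(b), np.cos(a) * np.cos(b), np.sin(b)])
    u = np.array([np.cos(a), -np.sin(a), 0.0])
    v = np.cross(d, u)  # = (sin a sin b, cos a sin b, -cos b)
    return u, v, d


def source_position(geom: AcquisitionGeometry) -> np.ndarray:
    """X-ray source position in world mm."""
    return -geom.sod * view_direction(geom)


def project_points(pts: np.ndarray, geom: AcquisitionGeometry) -> np.ndarray:
    """Perspective-project world points to detector pixel coordinates.

    Parameters
    ----------
    pts : (n, 3) or (3,) array
        World coordinates in mm.

    Returns
    -------
    (n, 2) or (2,) array of continuous ``(row, col)`` pixel coordinates.

    Raises
    ------
    GeometryError
        If any point is at or behind the source plane (non-positive depth
        along the view axis).
    """
    pts_in = np.asarray(pts, dtype=float)
    single = pts_in.ndim == 1
    pts = pts_in.reshape(-1, 3)
    u, v, d = detector_axes(geom)
    src = -geom.sod * d
    rel = pts - src
    depth = rel @ d
    if np.any(depth <= 0):
        raise GeometryError("point at or behind the source plane (depth <= 0)")
    mag = geom.sdd / depth  # perspective magnification at each depth
    u_mm = (rel @ u) * mag
    v_mm = (rel @ v) * mag
    pr, pc = geom.principal_point
    out = np.column_stack([pr + v_mm / geom.pixel_spacing, pc + u_mm / geom.pixel_spacing])
    return out[0] if single else out


def project_point(p, geom: AcquisitionGeometry) -> np.ndarray:
    """Project a single world point; returns ``(row, col)``."""
    return project_points(np.asarray(p, dtype=float).reshape(3), geom)


def backproject_ray(q, geom: AcquisitionGeometry):
    """Ray from the X-ray source through the detector point of pixel ``q``.

    Parameters
    ----------
    q : (row, col)
        Continuous pixel coordinates.

    Returns
    -------
    (origin, direction)
        ``origin`` is the source position (mm); ``direction`` is a unit
        vector pointing from the source toward the detector point.
    """
    row, col = float(q[0]), float(q[1])
    u, v, d = detector_axes(geom)
    src = -geom.sod * d
    pr, pc = geom.principal_point
    det_pt = (
        (geom.sdd - geom.sod) * d
        + (col - pc) * geom.pixel_spacing * u
        + (row - pr) * geom.pixel_spacing * v
    )
    direction = det_pt - src
    direction = direction / np.linalg.norm(direction)
    return src, direction
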