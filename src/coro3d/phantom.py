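"""Synthetic coronary phantoms: 3D centerlines, biplane renders, ground truth.

A phantom vessel is a smooth cubic-spline centerline through per-artery
canonical control points (gentle anterior-descending, circumflex or
right-coronary sweeps around the isocenter), randomly perturbed per control
point, with a linearly tapering lumen radius and optional Gaussian-profile
stenoses.  Rendering projects the centerline into a view and darkens
magnified discs on a bright background (intensity floors, not physical
attenuation — sufficient to exercise vesselness-based segmentation).  Table
panning between the two views is simulated by translating the 3D points in
the table (x-z) plane before rendering view 2.

Everything is deterministic given the spec and its seed; the phantom is the
package's only required data source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .curves import Centerline3D, arc_lengths, resample_polyline_step
from .geometry import AcquisitionGeometry, detector_axes, project_points
from .segmentation import EndpointPair

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CANONICAL_CONTROL_POINTS",
    "default_case_geometries",
    "generate_centerline",
    "render_view",
    "make_case",
    "make_template_library",
    "straight_tube_image",
]

# Canonical control points (mm, isocenter-centred world frame: x left,
# y anterior, z cranial).  Shapes are stylized but anatomically oriented:
# LAD sweeps anteriorly and caudally, LCX arcs leftward, RCA curves rightward.
CANONICAL_CONTROL_POINTS = {
    "LAD": np.array([
        [-5.0, 8.0, 25.0],
        [2.0, 16.0, 12.0],
        [8.0, 18.0, -2.0],
        [6.0, 14.0, -14.0],
        [0.0, 8.0, -25.0],
    ]),
    "LCX": np.array([
        [-3.0, 10.0, 20.0],
        [10.0, 14.0, 10.0],
        [18.0, 8.0, 0.0],
        [16.0, -2.0, -10.0],
        [8.0, -10.0, -18.0],
    ]),
    "RCA": np.array([
        [3.0, 12.0, 20.0],
        [-12.0, 14.0, 8.0],
        [-18.0, 4.0, -2.0],
        [-14.0, -8.0, -10.0],
        [-3.0, -12.0, -18.0],
    ]),
}

BACKGROUND_INTENSITY = 0.9
VESSEL_FLOOR_INTENSITY = 0.2
EDGE_WIDTH_PX = 1.0  # half-cosine edge transition width


@dataclass
class PhantomSpec:
    """Parameters of one synthetic vessel case.

    ``stenoses`` is a list of ``(center_fraction, severity_fraction,
    width_mm)`` tuples; a severity of 0.5 halves the local radius at the
    stenosis center.
    """

    artery_type: str = "LAD"
    seed: int = 0
    length_mm: float = 70.0
    proximal_radius_mm: float = 1.75
    distal_radius_mm: float = 1.0
    stenoses: list = field(default_factory=list)
    noise_sd: float = 0.0
    panning_mm: tuple = (0.0, 0.0)
    control_perturb_sd_mm: float = 3.0

    def __post_init__(self):
        if self.artery_type not in CANONICAL_CONTROL_POINTS:
            raise ValueError(f"unknown artery type {self.artery_type!r}")
        if self.length_mm <= 0 or self.proximal_radius_mm <= 0 or self.distal_radius_mm <= 0:
            raise ValueError("length and radii must be positive")
        for cf, sev, w in self.stenoses:
            if not (0 < cf < 1) or not (0 <= sev < 1) or w <= 0:
                raise ValueError("invalid stenosis parameters")


@dataclass
class GroundTruth:
    """Known truth accompanying a rendered phantom case."""

    centerline3d: Centerline3D
    endpoints1: EndpointPair
    endpoints2: EndpointPair
    mask1: np.ndarray
    mask2: np.ndarray
    panning_mm: tuple


def default_case_geometries():
    """A well-separated clinical biplane pair used for default phantom cases.

    Pixel spacing 0.35 mm gives a ~18 cm field of view on a 512x512 matrix,
    leaving room for the vessel plus table panning.
    """
    g1 = AcquisitionGeometry(alpha=30.0, beta=25.0, sod=750.0, sdd=1000.0,
                             pixel_spacing=0.35, image_size=(512, 512))
    g2 = AcquisitionGeometry(alpha=-30.0, beta=-15.0, sod=750.0, sdd=1000.0,
                             pixel_spacing=0.35, image_size=(512, 512))
    return g1, g2


def _spline_centerline(control: np.ndarray, step_mm: float = 1.0) -> np.ndarray:
    """Natural cubic spline through control points, arc-length resampled."""
    chord = arc_lengths(control)
    cs = CubicSpline(chord, control, axis=0)
    dense = cs(np.linspace(0.0, chord[-1], 50 * len(control)))
    return resample_polyline_step(dense, step_mm)


def generate_centerline(spec: PhantomSpec) -> Centerline3D:
    """Seeded random smooth centerline with tapered, optionally stenosed radii.

    Control points are perturbed with isotropic Gaussian noise
    (``control_perturb_sd_mm`` per coordinate), splined, resampled at 1 mm
    and uniformly scaled about the centroid so the total arc length equals
    ``length_mm``.  Radii taper linearly from proximal to distal and each
    stenosis multiplies them by ``1 - severity * exp(-(l - center)^2 /
    (2 * (width / 2.355)^2))`` (width is the FWHM in mm).
    """
    rng = np.random.default_rng(spec.seed)
    control = CANONICAL_CONTROL_POINTS[spec.artery_type].copy()
    control += rng.normal(0.0, spec.control_perturb_sd_mm, size=control.shape)
    pts = _spline_centerline(control)
    length = arc_lengths(pts)[-1]
    centroid = pts.mean(axis=0)
    pts = centroid + (pts - centroid) * (spec.length_mm / length)
    pts = resample_polyline_step(pts, 1.0)

    cum = arc_lengths(pts)
    frac = cum / cum[-1]
    radii = spec.proximal_radius_mm + frac * (spec.distal_radius_mm - spec.proximal_radius_mm)
    for center_frac, severity, width_mm in spec.stenoses:
        sigma = width_mm / 2.355
        radii = radii * (1.0 - severity * np.exp(-((cum - center_frac * cum[-1]) ** 2)
                                                 / (2.0 * sigma ** 2)))
    return Centerline3D(points=pts, radii_mm=radii)


def render_view(cl: Centerline3D, geom: AcquisitionGeometry, noise_sd: float = 0.0,
                panning_mm=(0.0, 0.0), rng=None):
    """Render one angiographic view of the vessel; returns (image, true mask).

    The centerline is translated by the in-table-plane panning, resampled
    densely, projected, and each sample darkens a disc of the magnified
    local radius with a 1 px half-cosine edge, accumulated by per-pixel
    minimum.  The true mask is the union of the hard (un-smoothed) discs.
    """
    rows, cols = geom.image_size
    t = np.array([panning_mm[0], 0.0, panning_mm[1]])
    _, _, d = detector_axes(geom)

    # dense resampling so projected discs overlap (~0.3 px spacing)
    mag0 = geom.sdd / geom.sod
    step_mm = 0.3 * geom.pixel_spacing / mag0
    dense_pts = resample_polyline_step(cl.points, step_mm) + t
    cum_orig = arc_lengths(cl.points)
    cum_dense = arc_lengths(dense_pts)
    radii = np.interp(cum_dense / cum_dense[-1], cum_orig / cum_orig[-1], cl.radii_mm)

    pix = project_points(dense_pts, geom)
    src = -geom.sod * d
    depth = (dense_pts - src) @ d
    r_px = radii * (geom.sdd / depth) / geom.pixel_spacing

    margin = r_px + EDGE_WIDTH_PX
    if (np.any(pix[:, 0] - margin < 0) or np.any(pix[:, 0] + margin > rows - 1)
            or np.any(pix[:, 1] - margin < 0) or np.any(pix[:, 1] + margin > cols - 1)):
        rmin, rmax = pix[:, 0].min(), pix[:, 0].max()
        cmin, cmax = pix[:, 1].min(), pix[:, 1].max()
        raise ValueError(
            "vessel outside the field of view: projected rows "
            f"[{rmin:.0f}, {rmax:.0f}], cols [{cmin:.0f}, {cmax:.0f}] on a {rows}x{cols} image"
        )

    image = np.full((rows, cols), BACKGROUND_INTENSITY)
    mask = np.zeros((rows, cols), dtype=bool)
    half = EDGE_WIDTH_PX / 2.0
    for (pr, pc), rp in zip(pix, r_px):
        w = int(np.ceil(rp + half)) + 1
        r0, r1 = int(np.floor(pr)) - w, int(np.floor(pr)) + w + 1
        c0, c1 = int(np.floor(pc)) - w, int(np.floor(pc)) + w + 1
        rr = np.arange(r0, r1)
        cc = np.arange(c0, c1)
        rho = np.hypot(rr[:, None] - pr, cc[None, :] - pc)
        patch = np.full(rho.shape, BACKGROUND_INTENSITY)
        inner = rho <= rp - half
        edge = (rho > rp - half) & (rho < rp + half)
        patch[inner] = VESSEL_FLOOR_INTENSITY
        blend = 0.5 * (1 - np.cos(np.pi * (rho[edge] - (rp - half)) / EDGE_WIDTH_PX))
        patch[edge] = VESSEL_FLOOR_INTENSITY + (BACKGROUND_INTENSITY - VESSEL_FLOOR_INTENSITY) * blend
        image[r0:r1, c0:c1] = np.minimum(image[r0:r1, c0:c1], patch)
        mask[r0:r1, c0:c1] |= rho <= rp

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        image = np.clip(image + rng.normal(0.0, noise_sd, image.shape), 0.0, 1.0)
    return image, mask


def make_case(spec: PhantomSpec, geom1: AcquisitionGeometry = None,
              geom2: AcquisitionGeometry = None):
    """Full biplane case: two rendered views plus ground truth.

    View 1 is rendered without panning; view 2 with the spec's in-table
    translation applied to the 3D points.  Endpoints are the projections of
    the true 3D vessel ends.  Returns ``(image1, image2, ground_truth)``.
    """
    if geom1 is None or geom2 is None:
        g1, g2 = default_case_geometries()
        geom1 = geom1 or g1
        geom2 = geom2 or g2
    cl = generate_centerline(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    img1, mask1 = render_view(cl, geom1, noise_sd=spec.noise_sd, rng=rng)
    img2, mask2 = render_view(cl, geom2, noise_sd=spec.noise_sd,
                              panning_mm=spec.panning_mm, rng=rng)
    t = np.array([spec.panning_mm[0], 0.0, spec.panning_mm[1]])
    e1 = project_points(np.array([cl.points[0], cl.points[-1]]), geom1)
    e2 = project_points(np.array([cl.points[0] + t, cl.points[-1] + t]), geom2)
    gt = GroundTruth(
        centerline3d=cl,
        endpoints1=EndpointPair(start=tuple(e1[0]), end=tuple(e1[1])),
        endpoints2=EndpointPair(start=tuple(e2[0]), end=tuple(e2[1])),
        mask1=mask1,
        mask2=mask2,
        panning_mm=tuple(spec.panning_mm),
    )
    return img1, img2, gt


def make_template_library(artery_type: str, n_models: int = 10, seed: int = 0,
                          perturb_sd_mm: float = 3.0) -> list:
    """Seeded perturbations of the canonical artery shape for template building."""
    if n_models < 2:
        raise ValueError("need at least 2 models")
    out = []
    for k in range(n_models):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, k]))
        spec = PhantomSpec(artery_type=artery_type, seed=0,
                           control_perturb_sd_mm=perturb_sd_mm,
                           length_mm=float(70.0 * rng.uniform(0.8, 1.2)))
        control = CANONICAL_CONTROL_POINTS[artery_type].copy()
        control += rng.normal(0.0, perturb_sd_mm, size=control.shape)
        pts = _spline_centerline(control)
        length = arc_lengths(pts)[-1]
        centroid = pts.mean(axis=0)
        pts = centroid + (pts - centroid) * (spec.length_mm / length)
        out.append(Centerline3D(points=resample_polyline_step(pts, 1.0)))
    return out


def straight_tube_image(shape=(128, 256), axis_row=64.0, width_px=9.0,
                        angle_deg=0.0, background=BACKGROUND_INTENSITY,
                        floor=VESSEL_FLOOR_INTENSITY):
    """Synthetic dark straight tube on a bright background; returns (image, mask).

    The tube axis passes through the image center at ``angle_deg`` from the
    horizontal (row = ``axis_row`` when the angle is zero); edges use the
    same 1 px half-cosine profile as the phantom renderer, so the true tube
    boundary (mask) sits exactly at the half-intensity level.
    """
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    th = np.deg2rad(angle_deg)
    # signed distance from the axis line through (axis_row, cols/2)
    dist = np.abs(np.cos(th) * (rr - axis_row) - np.sin(th) * (cc - (cols - 1) / 2.0))
    half_w = width_px / 2.0
    half = EDGE_WIDTH_PX / 2.0
    image = np.full(shape, background, dtype=float)
    inner = dist <= half_w - half
    edge = (dist > half_w - half) & (dist < half_w + half)
    image[inner] = floor
    blend = 0.5 * (1 - np.cos(np.pi * (dist[edge] - (half_w - half)) / EDGE_WIDTH_PX))
    image[edge] = floor + (background - floor) * blend
    mask = dist <= half_w
    return image, mask
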