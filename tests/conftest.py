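import numpy as np
import pytest

from coro3d.geometry import AcquisitionGeometry
from coro3d.phantom import straight_tube_image


@pytest.fixture(scope="session")
def biplane():
    """Well-separated clinical view pair used throughout the tests."""
    g1 = AcquisitionGeometry(alpha=30.0, beta=25.0, sod=750.0, sdd=1000.0,
                             pixel_spacing=0.35, image_size=(512, 512))
    g2 = AcquisitionGeometry(alpha=-30.0, beta=-15.0, sod=750.0, sdd=1000.0,
                             pixel_spacing=0.35, image_size=(512, 512))
    return g1, g2


@pytest.fixture(scope="session")
def tube():
    """Horizontal dark tube, width 9 px, axis at row 64, with its true mask."""
    image, mask = straight_tube_image(shape=(128, 256), axis_row=64.0, width_px=9.0)
    return image, mask


def random_geometry(rng, pixel_spacing=0.35):
    return AcquisitionGeometry(
        alpha=float(rng.uniform(-170, 170)),
        beta=float(rng.uniform(-40, 40)),
        sod=float(rng.uniform(600, 850)),
        sdd=float(rng.uniform(950, 1250)),
        pixel_spacing=pixel_spacing,
        image_size=(512, 512),
    )


def grid_search_triangulation(p1, p2, geom1, geom2, panning=(0.0, 0.0), n=100000):
    """Independent dense 1D search over ray depth, with parabolic refinement.

    Scans the view-1 ray's plausible depth range, projects each candidate
    (plus panning) into view 2, takes the depth minimizing the pixel distance
    to p2, and refines it with a parabola through the three samples around
    the discrete minimum.
    """
    from coro3d.geometry import backproject_ray, detector_axes, project_points

    src, e = backproject_ray(p1, geom1)
    t = np.array([panning[0], 0.0, panning[1]])
    s = np.linspace(0.1 * geom1.sod, 2.0 * geom1.sdd, n)
    pts = src[None] + s[:, None] * e[None] + t[None]
    # keep only candidates at positive view-2 depth (projectable)
    _, _, d2 = detector_axes(geom2)
    depth = (pts + geom2.sod * d2) @ d2
    valid = depth > 1.0
    s, pts = s[valid], pts[valid]
    n = len(s)
    pix = project_points(pts, geom2)
    d2 = ((pix - np.asarray(p2, dtype=float)[None]) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    if 0 < k < n - 1:
        a, b, c = d2[k - 1], d2[k], d2[k + 1]
        denom = a - 2 * b + c
        if denom > 0:
            s_star = s[k] + 0.5 * (a - c) / denom * (s[1] - s[0])
        else:
            s_star = s[k]
    else:
        s_star = s[k]
    point = src + s_star * e
    q = project_points((point + t).reshape(1, 3), geom2)[0]
    residual = float(np.linalg.norm(q - np.asarray(p2, dtype=float)))
    return point, residual
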