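"""2D vessel segmentation: vesselness, minimal-path centerline, diameters.

The segmentation chain for one angiogram is

1. multiscale Hessian (Frangi) vesselness to enhance the contrast-filled
   lumen (dark tubes on a bright background),
2. thresholding + connected-component selection to obtain a vessel mask,
3. a fast-marching minimal path between the proximal and distal endpoints,
   with front speed proportional to the distance to the nearest wall so the
   path runs along the vessel axis rather than hugging a border,
4. per-point diameter measurement by casting rays along the local normal to
   the two mask borders.

The eikonal equation |grad T| = 1/F is solved with a first-order upwind
fast-marching scheme on the pixel grid (speed zero outside the mask), and the
path is traced back from the distal endpoint by sub-pixel steepest descent on
the arrival-time field.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.morphology import skeletonize

from .curves import Centerline2D, resample_polyline_step

__all__ = [
    "SegmentationError",
    "EndpointPair",
    "frangi_vesselness",
    "segment_mask",
    "fast_marching_times",
    "extract_centerline",
    "measure_diameters",
    "heuristic_endpoints",
    "segment_view",
]

DEFAULT_SCALES = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
DEFAULT_BETA = 0.5
DEFAULT_THRESHOLD = 0.4  # fraction of the maximum vesselness
DEFAULT_SNAP_RADIUS = 10.0
SPEED_EPS = 0.1  # floor added to the wall-distance speed, in px


class SegmentationError(RuntimeError):
    """Raised when the vessel cannot be segmented from the given inputs."""


@dataclass(frozen=True)
class EndpointPair:
    """Proximal (catheter-tip side) and distal endpoints, pixel (row, col)."""

    start: tuple
    end: tuple

    def __post_init__(self):
        if tuple(self.start) == tuple(self.end):
            raise ValueError("endpoints must be distinct")


def frangi_vesselness(image, scales=DEFAULT_SCALES, beta=DEFAULT_BETA, c=None,
                      polarity="dark"):
    """Multiscale Frangi tubularity response in [0, 1].

    Per pixel and scale sigma, with sigma^2-normalized Hessian eigenvalues
    |l1| <= |l2|, the response is zero when l2 has the wrong sign for the
    requested polarity (dark vessels need l2 > 0), and otherwise

        exp(-R_B^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2)))

    with blobness R_B = l1/l2 and structureness S = sqrt(l1^2 + l2^2).  The
    returned map is the maximum over scales.

    Parameters
    ----------
    image : 2D array
        Grayscale intensities in [0, 1].
    scales : sequence of float
        Gaussian scales sigma in pixels.
    beta : float
        Blobness sensitivity.
    c : float or None
        Structureness sensitivity; None selects half the maximum Frobenius
        Hessian norm per scale.
    polarity : {"dark", "bright"}
        Whether vessels are darker or brighter than the background.
    """
    scales = list(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be a non-empty list of positive sigmas")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    img = np.asarray(image, dtype=float)
    if polarity == "bright":
        img = -img  # a dark ridge of -img; the l2 > 0 gate below then applies

    # sigma^2-normalized Hessian eigenvalues per scale; the structureness
    # constant c is shared across scales (half the max Frobenius norm over
    # the whole image) so that the across-scale maximum is comparable and
    # the response peaks at the vessel axis, not at small-scale edges.
    eigs = []
    s_max = 0.0
    for sigma in scales:
        hess = hessian_matrix(img, sigma=sigma, mode="reflect",
                              use_gaussian_derivatives=True)
        ev = hessian_matrix_eigvals(hess) * sigma ** 2
        ev = np.take_along_axis(ev, np.abs(ev).argsort(0), 0)  # |l1| <= |l2|
        eigs.append(ev)
        s_max = max(s_max, float(np.sqrt((ev ** 2).sum(0)).max()))
    if c is None and s_max <= 1e-12:
        return np.zeros_like(img)  # featureless image: zero Hessian everywhere
    cc = float(c) if c is not None else s_max / 2.0

    out = np.zeros_like(img)
    for ev in eigs:
        l1, l2 = ev[0], ev[1]
        l2_safe = np.where(l2 > 1e-10, l2, 1e-10)
        r_b = np.abs(l1) / l2_safe
        s2 = l1 ** 2 + l2 ** 2
        vals = np.exp(-r_b ** 2 / (2 * beta ** 2)) * (1.0 - np.exp(-s2 / (2 * cc ** 2)))
        vals[l2 <= 0] = 0.0  # wrong curvature sign for a dark vessel
        np.maximum(out, vals, out=out)
    return out


def _snap_to_mask(point, candidate_mask, snap_radius):
    """Nearest True pixel of ``candidate_mask`` within ``snap_radius`` of point."""
    r0, c0 = float(point[0]), float(point[1])
    rad = int(np.ceil(snap_radius))
    rows, cols = candidate_mask.shape
    rlo, rhi = max(0, int(r0) - rad), min(rows, int(r0) + rad + 2)
    clo, chi = max(0, int(c0) - rad), min(cols, int(c0) + rad + 2)
    window = candidate_mask[rlo:rhi, clo:chi]
    idx = np.argwhere(window)
    if len(idx) == 0:
        raise SegmentationError(
            f"no vessel pixel within snap radius {snap_radius} of point ({r0:.1f}, {c0:.1f})"
        )
    d = np.hypot(idx[:, 0] + rlo - r0, idx[:, 1] + clo - c0)
    k = int(np.argmin(d))
    if d[k] > snap_radius:
        raise SegmentationError(
            f"no vessel pixel within snap radius {snap_radius} of point ({r0:.1f}, {c0:.1f})"
        )
    return int(idx[k, 0] + rlo), int(idx[k, 1] + clo)


def segment_mask(vesselness, endpoints: EndpointPair, threshold=DEFAULT_THRESHOLD,
                 snap_radius=DEFAULT_SNAP_RADIUS):
    """Binary vessel mask: thresholded vesselness, endpoint-connected, hole-filled.

    The vesselness map is thresholded at ``threshold`` times its maximum; each
    endpoint is snapped to the nearest above-threshold pixel within
    ``snap_radius``; the connected component containing both endpoints is kept
    and its holes filled.

    Raises
    ------
    SegmentationError
        If an endpoint has no nearby above-threshold pixel, or the two
        endpoints land in different components.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    vess = np.asarray(vesselness, dtype=float)
    binary = vess > threshold * vess.max()
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    s = _snap_to_mask(endpoints.start, binary, snap_radius)
    e = _snap_to_mask(endpoints.end, binary, snap_radius)
    if labels[s] != labels[e]:
        raise SegmentationError("endpoints fall in different connected components")
    mask = labels == labels[s]
    return ndimage.binary_fill_holes(mask)


def fast_marching_times(speed: np.ndarray, mask: np.ndarray, start) -> np.ndarray:
    """First-order upwind fast-marching solution of |grad T| = 1/F.

    Arrival times are computed on the pixel grid from the ``start`` pixel,
    restricted to ``mask`` (infinite time outside).  Unit grid spacing.
    """
    rows, cols = speed.shape
    T = np.full((rows, cols), np.inf)
    state = np.zeros((rows, cols), dtype=np.uint8)  # 0 far, 1 trial, 2 accepted
    sr, sc = int(start[0]), int(start[1])
    if not mask[sr, sc]:
        raise SegmentationError("fast-marching start pixel outside the mask")
    T[sr, sc] = 0.0
    heap = [(0.0, sr, sc)]
    state[sr, sc] = 1
    neigh = ((-1, 0), (1, 0), (0, -1), (0, 1))
    while heap:
        t, r, c = heapq.heappop(heap)
        if state[r, c] == 2:
            continue
        state[r, c] = 2
        for dr, dc in neigh:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            if state[nr, nc] == 2 or not mask[nr, nc]:
                continue
            # upwind neighbors in each axis
            tx = min(
                T[nr - 1, nc] if nr > 0 else np.inf,
                T[nr + 1, nc] if nr < rows - 1 else np.inf,
            )
            ty = min(
                T[nr, nc - 1] if nc > 0 else np.inf,
                T[nr, nc + 1] if nc < cols - 1 else np.inf,
            )
            f = 1.0 / speed[nr, nc]
            a, b = (tx, ty) if tx <= ty else (ty, tx)
            if np.isinf(a):
                continue
            if b - a >= f:
                tn = a + f
            else:
                tn = 0.5 * (a + b + np.sqrt(max(0.0, 2 * f * f - (a - b) ** 2)))
            if tn < T[nr, nc]:
                T[nr, nc] = tn
                state[nr, nc] = 1
                heapq.heappush(heap, (tn, nr, nc))
    return T


def _trace_path(T, mask, start, end, step=0.25, max_steps=200000):
    """Steepest-descent path on the arrival-time field, from end back to start."""
    rows, cols = T.shape
    finite = np.isfinite(T)
    big = T[finite].max() * 2.0 + 10.0
    Tf = np.where(finite & mask, T, big)
    gr, gc = np.gradient(Tf)
    grid = (np.arange(rows), np.arange(cols))
    interp_T = RegularGridInterpolator(grid, Tf, bounds_error=False, fill_value=big)
    interp_gr = RegularGridInterpolator(grid, gr, bounds_error=False, fill_value=0.0)
    interp_gc = RegularGridInterpolator(grid, gc, bounds_error=False, fill_value=0.0)

    p = np.array([float(end[0]), float(end[1])])
    s = np.array([float(start[0]), float(start[1])])
    path = [p.copy()]
    for _ in range(max_steps):
        if np.linalg.norm(p - s) <= max(0.75, step):
            break
        g = np.array([interp_gr(p).item(), interp_gc(p).item()])
        gn = np.linalg.norm(g)
        moved = False
        if gn > 1e-12:
            cand = p - step * g / gn
            if interp_T(cand).item() < interp_T(p).item():
                p = cand
                moved = True
        if not moved:
            # fall back to the lowest-T integer neighbor (handles flat spots
            # and the immediate vicinity of the start)
            ri, ci = int(round(p[0])), int(round(p[1]))
            best, bt = None, float(Tf[ri, ci])
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nr, nc = ri + dr, ci + dc
                    if 0 <= nr < rows and 0 <= nc < cols and Tf[nr, nc] < bt:
                        best, bt = (nr, nc), float(Tf[nr, nc])
            if best is None:
                break
            p = np.array(best, dtype=float)
        path.append(p.copy())
    path.append(s.copy())
    return np.array(path[::-1])  # proximal -> distal


def extract_centerline(mask, endpoints: EndpointPair, step_px=1.0,
                       snap_radius=DEFAULT_SNAP_RADIUS) -> Centerline2D:
    """Fast-marching minimal-path centerline between the endpoints.

    The front speed is F(x) = D(x) + eps with D the Euclidean distance to the
    mask boundary (zero speed outside the mask), which centers the fastest
    path in the lumen.  The traced path is resampled to uniform ``step_px``
    arc-length spacing.  Diameters are not filled here.
    """
    mask = np.asarray(mask, dtype=bool)
    s = _snap_to_mask(endpoints.start, mask, snap_radius)
    e = _snap_to_mask(endpoints.end, mask, snap_radius)
    dist = ndimage.distance_transform_edt(mask)
    speed = dist + SPEED_EPS
    T = fast_marching_times(speed, mask, s)
    if not np.isfinite(T[e]):
        raise SegmentationError("distal endpoint unreachable from the proximal endpoint")
    path = _trace_path(T, mask, s, e)
    # anchor the path exactly at the supplied (continuous) endpoints: they are
    # trusted landmarks, and snapping to the pixel grid must not move them
    path[0] = np.asarray(endpoints.start, dtype=float)
    path[-1] = np.asarray(endpoints.end, dtype=float)
    # drop duplicate consecutive points before resampling
    keep = np.concatenate([[True], np.linalg.norm(np.diff(path, axis=0), axis=1) > 1e-9])
    path = path[keep]
    resampled = resample_polyline_step(path, step_px)
    resampled[0], resampled[-1] = path[0], path[-1]
    return Centerline2D(points=resampled)


def measure_diameters(centerline: Centerline2D, mask, max_dist=40.0,
                      ray_step=0.1) -> Centerline2D:
    """Fill per-point diameters by normal ray casting to the two mask borders.

    At each interior point the tangent comes from central differences of the
    neighboring points; rays are cast along +/- the normal, sampling the mask
    with bilinear interpolation, and the first 0.5-crossing gives a sub-pixel
    one-sided border distance.  The diameter is the sum of the two one-sided
    distances.  Endpoints copy their nearest interior value; points whose
    rays never exit within ``max_dist`` are flagged and interpolated from
    their neighbors.
    """
    mask_f = np.asarray(mask, dtype=float)
    rows, cols = mask_f.shape
    grid = (np.arange(rows), np.arange(cols))
    interp = RegularGridInterpolator(grid, mask_f, bounds_error=False, fill_value=0.0)
    pts = centerline.points
    n = len(pts)
    diam = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)

    rho = np.arange(ray_step, max_dist, ray_step)

    def one_sided(p, direction):
        samples = p[None, :] + rho[:, None] * direction[None, :]
        vals = interp(samples)
        below = np.nonzero(vals < 0.5)[0]
        if len(below) == 0:
            return None
        k = below[0]
        if k == 0:
            return rho[0]
        # linear interpolation of the 0.5 crossing between samples k-1 and k
        v0, v1 = vals[k - 1], vals[k]
        frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.0
        return rho[k - 1] + frac * ray_step

    for i in range(1, n - 1):
        tang = pts[i + 1] - pts[i - 1]
        norm = np.linalg.norm(tang)
        if norm == 0:
            flagged[i] = True
            continue
        tang /= norm
        normal = np.array([-tang[1], tang[0]])
        d_plus = one_sided(pts[i], normal)
        d_minus = one_sided(pts[i], -normal)
        if d_plus is None or d_minus is None:
            flagged[i] = True
        else:
            diam[i] = d_plus + d_minus

    interior = np.nonzero(~np.isnan(diam))[0]
    if len(interior) == 0:
        raise SegmentationError("no valid diameter measurement along the centerline")
    # interpolate flagged interior points, copy nearest interior value at ends
    bad = np.nonzero(np.isnan(diam))[0]
    diam[bad] = np.interp(bad, interior, diam[interior])
    return Centerline2D(points=pts, diameters_px=diam, flagged=flagged)


def heuristic_endpoints(mask, entry_border="top") -> EndpointPair:
    """Endpoints as the extremities of the longest skeleton geodesic.

    The mask is skeletonized; a double breadth-first sweep over the
    8-connected skeleton graph finds (approximately) the longest geodesic
    path; its two extremities are the endpoints.  The proximal one is the
    extremity closer to the configured catheter-entry border of the image
    (default the top edge).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    skel = skeletonize(mask)
    pix = np.argwhere(skel)
    if len(pix) < 2:
        raise SegmentationError("mask skeleton has fewer than 2 pixels")
    skel_set = set(map(tuple, pix))

    def bfs_farthest(src):
        from collections import deque

        seen = {src: 0}
        q = deque([src])
        far = src
        while q:
            r, c = q.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nb = (r + dr, c + dc)
                    if nb in skel_set and nb not in seen:
                        seen[nb] = seen[(r, c)] + 1
                        if seen[nb] > seen[far]:
                            far = nb
                        q.append(nb)
        return far, seen

    a, _ = bfs_farthest(tuple(pix[0]))
    b, dist_a = bfs_farthest(a)

    def extend_to_boundary(tip, dist):
        # skeletonization erodes the line ends; walk the tip outward along
        # the local end direction until the mask boundary
        back = [p for p, d in dist.items() if dist[tip] - 6 <= d < dist[tip]]
        if not back:
            return tip
        anchor = min(back, key=lambda p: dist[p])
        direction = np.array(tip, dtype=float) - np.array(anchor, dtype=float)
        norm = np.linalg.norm(direction)
        if norm == 0:
            return tip
        direction /= norm
        p = np.array(tip, dtype=float)
        while True:
            nxt = p + direction
            r, c = int(round(nxt[0])), int(round(nxt[1]))
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                break
            p = nxt
        return (int(round(p[0])), int(round(p[1])))

    _, dist_b = bfs_farthest(b)
    a = extend_to_boundary(a, dist_b)
    b = extend_to_boundary(b, dist_a)

    rows, cols = mask.shape
    border_dist = {
        "top": lambda p: p[0],
        "bottom": lambda p: rows - 1 - p[0],
        "left": lambda p: p[1],
        "right": lambda p: cols - 1 - p[1],
    }
    if entry_border not in border_dist:
        raise ValueError(f"unknown entry border {entry_border!r}")
    key = border_dist[entry_border]
    start, end = (a, b) if key(a) <= key(b) else (b, a)
    return EndpointPair(start=start, end=end)


def segment_view(image, endpoints: EndpointPair, scales=DEFAULT_SCALES,
                 beta=DEFAULT_BETA, c=None, threshold=DEFAULT_THRESHOLD,
                 snap_radius=DEFAULT_SNAP_RADIUS, step_px=1.0, polarity="dark"):
    """Full single-view chain: vesselness -> mask -> centerline -> diameters.

    Returns ``(centerline, mask, vesselness)``.
    """
    vess = frangi_vesselness(image, scales=scales, beta=beta, c=c, polarity=polarity)
    mask = segment_mask(vess, endpoints, threshold=threshold, snap_radius=snap_radius)
    cl = extract_centerline(mask, endpoints, step_px=step_px, snap_radius=snap_radius)
    cl = measure_diameters(cl, mask)
    return cl, mask, vess
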