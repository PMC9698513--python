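"""Square-marker detection in camera frames.

Four-stage pipeline: (1) local adaptive thresholding into a binary
image, (2) contour extraction and polygonal approximation keeping only
convex quadrilaterals, (3) perspective removal and grid binarization of
each candidate, (4) dictionary matching under all four rotations.

Image coordinate convention: origin at the top-left pixel centre,
x rightward, y downward, units pixels.  Quad corners are ordered
counter-clockwise on screen starting at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .camera_pose import homography_dlt, PoseEstimationError
from .marker_codec import MarkerDictionary, match_candidate

__all__ = [
    "DetectorParams",
    "QuadCandidate",
    "Detection",
    "adaptive_threshold",
    "extract_quads",
    "rectify_and_decode",
    "detect",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detection parameters (all config-exposed).

    window : adaptive threshold window, odd pixels.
    offset : threshold offset below the local mean, intensity units.
    min_area : minimum candidate quad area, px^2.
    epsilon_frac : polygonal approximation tolerance as a fraction of
        the contour perimeter.
    min_corner_sep : minimum pairwise corner separation, px.
    samples_per_cell : sample points per cell side during binarization.
    border_min_frac : fraction of border samples that must be foreground.
    refine_corners : enable sub-pixel edge-based corner refinement.
    """

    window: int = 23
    offset: float = 7.0
    min_area: float = 100.0
    epsilon_frac: float = 0.05
    min_corner_sep: float = 5.0
    samples_per_cell: int = 5
    border_min_frac: float = 0.90
    refine_corners: bool = True


@dataclass(frozen=True)
class QuadCandidate:
    """Convex quadrilateral candidate; corners (4, 2) float pixels."""

    corners: np.ndarray

    @property
    def area(self) -> float:
        return _polygon_area(self.corners)


@dataclass(frozen=True)
class Detection:
    """A decoded marker: id, canonical-order corners, decode metadata."""

    id: int
    corners: np.ndarray       # corner 0 = marker's canonical top-left
    decode_rotation: int      # quarter-turns undone during matching
    hamming: int = 0          # payload distance to matched codeword
    area: float = field(default=0.0, repr=False)


def _polygon_area(corners: np.ndarray) -> float:
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def adaptive_threshold(gray: np.ndarray, window: int = 23,
                       offset: float = 7.0) -> np.ndarray:
    """Mean-relative local threshold; True where intensity < mean - offset.

    The comparison is against the mean over a ``window x window``
    neighbourhood (reflect-padded at the borders), so the result is
    invariant to slowly varying illumination.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("adaptive_threshold expects a single-channel image")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(gray.shape):
        raise ValueError("window larger than the image")
    local_mean = ndimage.uniform_filter(gray, size=window, mode="reflect")
    return gray < (local_mean - offset)


def _order_ccw_from_topleft(corners: np.ndarray) -> np.ndarray:
    """Order corners counter-clockwise on screen starting nearest top-left."""
    c = corners.mean(axis=0)
    # screen-CCW = decreasing atan2 angle in y-down coordinates
    ang = np.arctan2(corners[:, 1] - c[1], corners[:, 0] - c[0])
    order = np.argsort(-ang)
    ordered = corners[order]
    start = int(np.argmin(ordered.sum(axis=1)))
    return np.roll(ordered, -start, axis=0)


def _is_convex(corners: np.ndarray) -> bool:
    signs = []
    for i in range(4):
        a = corners[(i + 1) % 4] - corners[i]
        b = corners[(i + 2) % 4] - corners[(i + 1) % 4]
        signs.append(np.sign(a[0] * b[1] - a[1] * b[0]))
    signs = [s for s in signs if s != 0]
    return len(signs) == 4 and len(set(signs)) == 1


def _corners_from_contour(points: np.ndarray, corners: np.ndarray
                          ) -> np.ndarray:
    """Re-derive quad corners by TLS line fits to the dense contour.

    Polygonal approximation only identifies which 4 edges exist; its
    vertex placement can be far from the true corners.  Each contour
    point is assigned to its nearest approximate edge, points close to
    the corners are dropped, a total-least-squares line is fit per edge,
    and corners are re-computed as adjacent line intersections.
    """
    n = len(corners)
    d2 = np.empty((n, len(points)))
    for i in range(n):
        p0, p1 = corners[i], corners[(i + 1) % n]
        e = p1 - p0
        ln2 = float(e @ e)
        if ln2 < 1e-12:
            return corners
        t = np.clip(((points - p0) @ e) / ln2, 0.0, 1.0)
        proj = p0 + t[:, None] * e
        d2[i] = ((points - proj) ** 2).sum(axis=1)
    assign = np.argmin(d2, axis=0)
    lines = []
    for i in range(n):
        pts = points[assign == i]
        p0, p1 = corners[i], corners[(i + 1) % n]
        e = p1 - p0
        length = np.linalg.norm(e)
        t = (pts - p0) @ e / (length * length)
        pts = pts[(t > 0.12) & (t < 0.88)]  # keep clear of the corners
        if len(pts) < 4:
            return corners
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        lines.append((c, vt[0]))
    out = []
    for i in range(n):
        c0, d0 = lines[(i - 1) % n]
        c1, d1 = lines[i]
        A = np.column_stack([d0, -d1])
        if abs(np.linalg.det(A)) < 1e-9:
            return corners
        s = np.linalg.solve(A, c1 - c0)
        out.append(c0 + s[0] * d0)
    return np.array(out)


def extract_quads(binary: np.ndarray, min_area: float = 100.0,
                  epsilon_frac: float = 0.05,
                  min_corner_sep: float = 5.0) -> list[QuadCandidate]:
    """Outer contours of foreground components, kept if they reduce to
    a convex 4-vertex polygon of sufficient area.

    Contours are traced per connected component (outer boundary only;
    interior child contours of a marker's payload are never candidates),
    then simplified with Douglas-Peucker at ``epsilon_frac x perimeter``.
    """
    binary = np.asarray(binary, bool)
    labels, n = ndimage.label(binary)
    out: list[QuadCandidate] = []
    slices = ndimage.find_objects(labels)
    for idx in range(n):
        sl = slices[idx]
        if sl is None:
            continue
        pad_mask = np.pad(labels[sl] == idx + 1, 1)
        if pad_mask.sum() < min_area:
            continue
        # fill interior holes so only the outer boundary is traced
        pad_mask = ndimage.binary_fill_holes(pad_mask)
        contours = measure.find_contours(pad_mask.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary
        # Douglas-Peucker anchors the endpoints of a closed contour, so
        # rotate the start to the point farthest from the centroid (a
        # guaranteed vertex of a convex outline) before simplifying
        ring = contour[:-1] if np.allclose(contour[0], contour[-1]) \
            else contour
        start = int(np.argmax(((ring - ring.mean(axis=0)) ** 2).sum(axis=1)))
        ring = np.roll(ring, -start, axis=0)
        contour = np.vstack([ring, ring[:1]])
        per = np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))
        approx = measure.approximate_polygon(contour, epsilon_frac * per)
        if len(approx) > 1 and np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) != 4:
            continue
        # contour coords are (row, col) in the padded crop -> image (x, y)
        corners = np.column_stack([
            approx[:, 1] - 1 + sl[1].start,
            approx[:, 0] - 1 + sl[0].start,
        ]).astype(float)
        if not _is_convex(corners):
            continue
        contour_xy = np.column_stack([
            contour[:, 1] - 1 + sl[1].start,
            contour[:, 0] - 1 + sl[0].start])
        fitted = _corners_from_contour(contour_xy, corners)
        if _is_convex(fitted):
            corners = fitted
        if _polygon_area(corners) < min_area:
            continue
        d = np.linalg.norm(corners - np.roll(corners, -1, axis=0), axis=1)
        if d.min() < min_corner_sep:
            continue
        out.append(QuadCandidate(corners=_order_ccw_from_topleft(corners)))
    return out


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    h, w = img.shape
    x = np.clip(x, 0, w - 1.001)
    y = np.clip(y, 0, h - 1.001)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    i = img.astype(float)
    return (i[y0, x0] * (1 - fx) * (1 - fy) + i[y0, x0 + 1] * fx * (1 - fy)
            + i[y0 + 1, x0] * (1 - fx) * fy + i[y0 + 1, x0 + 1] * fx * fy)


def refine_corners_subpixel(gray: np.ndarray, corners: np.ndarray,
                            n_samples: int = 24, half_range: float = 3.0
                            ) -> np.ndarray:
    """Sub-pixel corner refinement by edge-profile line intersection.

    For each quad edge, intensity profiles are sampled along the edge
    normal; the sub-pixel crossing of the mid-level between the inner and
    outer intensities is located per profile, a total-least-squares line is
    fit to the crossings, and refined corners are the intersections of
    adjacent edge lines.  Invariant under affine intensity maps since the
    mid-level is computed per profile.
    """
    gray = np.asarray(gray, float)
    lines = []
    for i in range(4):
        p0, p1 = corners[i], corners[(i + 1) % 4]
        edge = p1 - p0
        length = np.linalg.norm(edge)
        if length < 1e-6:
            return corners
        tang = edge / length
        normal = np.array([-tang[1], tang[0]])
        # sample away from the corners where the edge model is valid
        ts = np.linspace(0.2, 0.8, n_samples)
        pts = []
        offs = np.linspace(-half_range, half_range, 13)
        for t in ts:
            base = p0 + t * edge
            xs = base[0] + offs * normal[0]
            ys = base[1] + offs * normal[1]
            prof = _bilinear(gray, xs, ys)
            lo, hi = prof.min(), prof.max()
            if hi - lo < 1e-6:
                continue
            mid = 0.5 * (lo + hi)
            sgn = prof >= mid
            cross = np.nonzero(sgn[:-1] != sgn[1:])[0]
            if len(cross) != 1:
                continue  # ambiguous profile (clutter) -> skip sample
            # gradient-centroid location: less phase bias than the
            # mid-level crossing of the interpolated profile
            g = np.diff(prof)
            if abs(g.sum()) < 0.25 * (hi - lo):
                continue
            centers = 0.5 * (offs[:-1] + offs[1:])
            off = float((centers * g).sum() / g.sum())
            pts.append(base + off * normal)
        if len(pts) < max(4, n_samples // 3):
            return corners  # unreliable edges: keep integer-level corners
        pts = np.array(pts)
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        direction = vt[0]
        lines.append((centroid, direction))
    refined = []
    for i in range(4):
        c0, d0 = lines[(i - 1) % 4]
        c1, d1 = lines[i]
        A = np.column_stack([d0, -d1])
        if abs(np.linalg.det(A)) < 1e-9:
            return corners
        s = np.linalg.solve(A, c1 - c0)
        refined.append(c0 + s[0] * d0)
    refined = np.array(refined)
    if np.max(np.linalg.norm(refined - corners, axis=1)) > half_range:
        return corners  # refinement wandered off: reject
    return refined


def rectify_and_decode(gray: np.ndarray, quad: QuadCandidate,
                       dictionary: MarkerDictionary,
                       params: DetectorParams = DetectorParams()
                       ):
    """Undo perspective, binarize a (grid_size+2)^2 grid, match.

    Maps the quad corners to the canonical bordered square with a 4-point
    homography, samples each cell at ``samples_per_cell^2`` interior
    points, bit-assigns by majority against an adaptive mid-level, checks
    the black border, and delegates payload matching to the dictionary.

    Returns ``(id, rotation, hamming)`` or ``None`` (border failure,
    no dictionary match, or degenerate quad).
    """
    cells = dictionary.grid_size + 2
    canon = np.array([[0.0, 0.0], [0.0, cells], [cells, cells], [cells, 0.0]])
    try:
        H = homography_dlt(canon, quad.corners)
    except PoseEstimationError:
        return None
    s = params.samples_per_cell
    # sample point lattice in canonical coordinates, cell-interior offsets
    off = (np.arange(s) + 0.5) / s
    ox, oy = np.meshgrid(off, off)
    cell_x, cell_y = np.meshgrid(np.arange(cells), np.arange(cells))
    sx = (cell_x[..., None, None] + ox[None, None]).ravel()
    sy = (cell_y[..., None, None] + oy[None, None]).ravel()
    pts = np.column_stack([sx, sy, np.ones_like(sx)]) @ H.T
    with np.errstate(divide="ignore", invalid="ignore"):
        px = pts[:, 0] / pts[:, 2]
        py = pts[:, 1] / pts[:, 2]
    if not np.all(np.isfinite(px)) or not np.all(np.isfinite(py)):
        return None
    vals = _bilinear(np.asarray(gray, float), px, py)
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-6:
        thr = lo + 0.5  # uniform patch: everything on one side
    else:
        thr = 0.5 * (lo + hi)
    dark = (vals < thr).reshape(cells, cells, s * s)
    frac = dark.mean(axis=2)  # dark fraction per cell, indexed [y, x]
    bits = frac > 0.5
    border_frac = np.concatenate([
        frac[0], frac[-1], frac[1:-1, 0], frac[1:-1, -1]]).mean()
    if border_frac < params.border_min_frac:
        return None
    payload = bits[1:-1, 1:-1]
    matched = match_candidate(payload, dictionary)
    if matched is None:
        return None
    marker_id, rotation = matched
    code = np.rot90(dictionary.codewords[marker_id], rotation)
    hamming = int(np.sum(payload != code))
    return marker_id, rotation, hamming


def detect(image: np.ndarray, dictionary: MarkerDictionary,
           params: DetectorParams = DetectorParams()) -> list[Detection]:
    """Full pipeline: threshold -> quads -> rectify/decode -> dedupe.

    Accepts grayscale or RGB input (RGB is reduced by the standard
    luminance weights).  Duplicate candidates decoding to the same id are
    collapsed to the lowest decode Hamming distance, ties broken by
    larger quad area.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    gray = img.astype(float)
    binary = adaptive_threshold(gray, params.window, params.offset)
    quads = extract_quads(binary, params.min_area, params.epsilon_frac,
                          params.min_corner_sep)
    best: dict[int, Detection] = {}
    for quad in quads:
        corners = quad.corners
        if params.refine_corners:
            corners = refine_corners_subpixel(gray, corners)
            quad = QuadCandidate(corners=corners)
        decoded = rectify_and_decode(gray, quad, dictionary, params)
        if decoded is None:
            continue
        marker_id, rotation, hamming = decoded
        canonical = np.roll(corners, -rotation, axis=0)
        det = Detection(id=marker_id, corners=canonical,
                        decode_rotation=rotation, hamming=hamming,
                        area=_polygon_area(corners))
        prev = best.get(marker_id)
        if (prev is None or hamming < prev.hamming
                or (hamming == prev.hamming and det.area > prev.area)):
            best[marker_id] = det
    return [best[k] for k in sorted(best)]
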