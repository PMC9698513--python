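"""Pinhole camera model and 6-DoF planar marker pose estimation.

Pose is recovered from the four detected marker corners and the known
printed side length by iteratively minimizing the corner reprojection
error: a homography from the canonical (planar) marker corners to the
image is decomposed into an initial rotation + translation, then a
Levenberg-Marquardt refinement over a 6-parameter pose (axis-angle
rotation + translation) drives the RMS pixel residual to a minimum.

No lens distortion is modelled; intrinsics are a plain pinhole
``(fx, fy, cx, cy)`` record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraIntrinsics",
    "Pose",
    "MarkerGeometry",
    "project",
    "estimate_pose",
    "homography_dlt",
    "PoseEstimationError",
]


class PoseEstimationError(ValueError):
    """Degenerate geometry (collinear corners, points behind camera)."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels; no distortion terms."""

    fx: float
    fy: float
    cx: float
    cy: float
    image_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0.0, self.cx],
                         [0.0, self.fy, self.cy],
                         [0.0, 0.0, 1.0]])

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        size = d.get("image_size")
        return cls(fx=float(d["fx"]), fy=float(d["fy"]),
                   cx=float(d["cx"]), cy=float(d["cy"]),
                   image_size=tuple(size) if size else None)

    def to_dict(self) -> dict:
        d = {"fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy}
        if self.image_size is not None:
            d["image_size"] = list(self.image_size)
        return d


@dataclass(frozen=True)
class Pose:
    """Rigid transform of the marker relative to the camera (metres)."""

    rotation: np.ndarray   # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector, camera frame

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def transform(self, points3d: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points3d, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first."""
        return Pose(rotation=self.rotation @ other.rotation,
                    translation=self.rotation @ other.translation
                    + self.translation)

    def inverse(self) -> "Pose":
        return Pose(rotation=self.rotation.T,
                    translation=-self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": [float(v) for v in self.rotation.flatten()],
                "translation": [float(v) for v in self.translation],
                "units": "m"}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(rotation=np.array(d["rotation"], float).reshape(3, 3),
                   translation=np.array(d["translation"], float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class MarkerGeometry:
    """Physical square marker: side length in metres, corners at z = 0.

    Canonical corner order is counter-clockwise in the marker plane when
    viewed frontally, starting at the top-left corner, matching the corner
    order emitted by the detector:
    top-left, bottom-left, bottom-right, top-right in marker coordinates
    (x right, y down in the rendered bitmap; projected with y image-down).
    """

    side_length: float

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")

    @property
    def corners(self) -> np.ndarray:
        h = self.side_length / 2.0
        # x right, y down (image convention), z out of the marker plane
        return np.array([[-h, -h, 0.0],
                         [-h, +h, 0.0],
                         [+h, +h, 0.0],
                         [+h, -h, 0.0]])


def project(points3d: np.ndarray, pose: Pose,
            intrinsics: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of 3-D points through a pose; pixels (u, v)."""
    cam = pose.transform(points3d)
    z = cam[:, 2]
    if np.any(z <= 1e-12):
        raise PoseEstimationError("point at or behind the camera plane")
    u = intrinsics.fx * cam[:, 0] / z + intrinsics.cx
    v = intrinsics.fy * cam[:, 1] / z + intrinsics.cy
    return np.column_stack([u, v])


def homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform homography from >= 4 point pairs.

    Hartley-normalized; returns H with H[2,2] scaled so ||H|| = 1 up to
    sign.  Raises :class:`PoseEstimationError` for degenerate input.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape[0] < 4:
        raise PoseEstimationError("need at least 4 correspondences")

    def normalize(pts):
        c = pts.mean(axis=0)
        d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
        if d < 1e-12:
            raise PoseEstimationError("degenerate (coincident) points")
        s = np.sqrt(2.0) / d
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return ph[:, :2], T

    sn, Ts = normalize(src)
    dn, Td = normalize(dst)
    rows = []
    for (x, y), (u, v) in zip(sn, dn):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.array(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-10 * s[0]:
        raise PoseEstimationError("degenerate correspondence geometry")
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    sv = np.linalg.svd(H, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:  # rank-deficient map: collinear points
        raise PoseEstimationError("degenerate correspondence geometry")
    return H / np.linalg.norm(H)


def _pose_from_homography(H: np.ndarray, intrinsics: CameraIntrinsics
                          ) -> Pose:
    """Planar decomposition K^-1 H = [r1 r2 t] up to scale."""
    M = np.linalg.inv(intrinsics.matrix) @ H
    n1, n2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    if n1 < 1e-12 or n2 < 1e-12:
        raise PoseEstimationError("degenerate homography")
    scale = 2.0 / (n1 + n2)
    M = M * scale
    if M[2, 2] < 0:  # marker must be in front of the camera
        M = -M
    r1, r2, t = M[:, 0], M[:, 1], M[:, 2]
    # nearest rotation to [r1 r2 r1xr2] via SVD
    R0 = np.column_stack([r1, r2, np.cross(r1, r2)])
    u, _, vt = np.linalg.svd(R0)
    R = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    return Pose(rotation=R, translation=t)


def _residuals(params: np.ndarray, corners3d: np.ndarray,
               observed: np.ndarray, intrinsics: CameraIntrinsics
               ) -> np.ndarray:
    R = Rotation.from_rotvec(params[:3]).as_matrix()
    t = params[3:]
    cam = corners3d @ R.T + t
    z = np.maximum(cam[:, 2], 1e-9)
    u = intrinsics.fx * cam[:, 0] / z + intrinsics.cx
    v = intrinsics.fy * cam[:, 1] / z + intrinsics.cy
    return np.concatenate([u - observed[:, 0], v - observed[:, 1]])


def _levenberg_marquardt(params0, corners3d, observed, intrinsics,
                         max_iter=100, cost_tol=1e-10, lam0=1e-3):
    """Small dense LM over the 6-parameter pose; central-difference Jacobian.

    Returns (params, cost_history, converged); the history contains the cost
    after every ACCEPTED step, so it is non-increasing by construction.
    """
    params = np.asarray(params0, float).copy()
    r = _residuals(params, corners3d, observed, intrinsics)
    cost = float(r @ r)
    history = [cost]
    lam = lam0
    converged = False
    for _ in range(max_iter):
        J = np.empty((r.size, 6))
        h = 1e-7
        for k in range(6):
            dp = np.zeros(6)
            dp[k] = h
            rp = _residuals(params + dp, corners3d, observed, intrinsics)
            rm = _residuals(params - dp, corners3d, observed, intrinsics)
            J[:, k] = (rp - rm) / (2 * h)
        JTJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _try in range(25):
            try:
                step = np.linalg.solve(JTJ + lam * np.diag(np.diag(JTJ))
                                       + 1e-15 * np.eye(6), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = params + step
            rc = _residuals(cand, corners3d, observed, intrinsics)
            cc = float(rc @ rc)
            if cc < cost:
                params, r, prev, cost = cand, rc, cost, cc
                history.append(cost)
                lam = max(lam / 10, 1e-12)
                accepted = True
                if prev - cost < cost_tol:
                    converged = True
                break
            lam *= 10
        if not accepted:
            converged = True  # no descent direction left
            break
        if converged:
            break
    return params, history, converged


def _alternative_inits(pose: Pose) -> list[np.ndarray]:
    """Extra starting points mirroring the marker tilt (planar ambiguity)."""
    rv = Rotation.from_matrix(pose.rotation).as_rotvec()
    alts = []
    for flip in ([-1, -1, 1], [-1, 1, 1], [1, -1, 1]):
        alts.append(np.concatenate([rv * flip, pose.translation]))
    return alts


def estimate_pose(corners_px: np.ndarray, geometry: MarkerGeometry,
                  intrinsics: CameraIntrinsics, max_iter: int = 100,
                  cost_tol: float = 1e-10, return_history: bool = False):
    """Marker pose from its four observed corners.

    Parameters
    ----------
    corners_px : (4, 2) array
        Detected corners in canonical order (matching
        ``MarkerGeometry.corners``).
    geometry : MarkerGeometry
        Known printed marker size.
    intrinsics : CameraIntrinsics
        Pinhole intrinsics.

    Returns
    -------
    (Pose, rmse) or (Pose, rmse, history) with ``return_history``;
    ``rmse`` is the RMS corner reprojection residual in pixels.

    Raises
    ------
    PoseEstimationError
        For collinear/degenerate corner configurations.
    """
    corners_px = np.asarray(corners_px, float)
    if corners_px.shape != (4, 2):
        raise PoseEstimationError("need exactly 4 corner points")
    c3 = geometry.corners
    H = homography_dlt(c3[:, :2], corners_px)
    init = _pose_from_homography(H, intrinsics)
    p0 = np.concatenate([
        Rotation.from_matrix(init.rotation).as_rotvec(), init.translation])

    best = None
    starts = [p0]
    params, history, _ = _levenberg_marquardt(
        p0, c3, corners_px, intrinsics, max_iter, cost_tol)
    rmse = np.sqrt(history[-1] / 8.0)
    best = (params, history, rmse)
    if rmse > 1e-3:  # possible planar two-fold ambiguity: try mirrored inits
        for alt in _alternative_inits(init):
            pa, ha, _ = _levenberg_marquardt(
                alt, c3, corners_px, intrinsics, max_iter, cost_tol)
            ra = np.sqrt(ha[-1] / 8.0)
            if ra < best[2]:
                best = (pa, ha, ra)
        starts.extend(_alternative_inits(init))

    params, history, rmse = best
    pose = Pose(rotation=Rotation.from_rotvec(params[:3]).as_matrix(),
                translation=params[3:])
    if pose.translation[2] <= 0:
        raise PoseEstimationError("estimated marker behind the camera")
    if return_history:
        return pose, float(rmse), history
    return pose, float(rmse)
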