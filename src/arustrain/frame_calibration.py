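"""Two-coordinate-frame calibration from four registered joints.

The engine tracks the probe marker in the camera/marker basis (A) and the
learner's body joints in the body-tracking basis (BT).  Placing the marker
at four joints (left shoulder, left elbow, left hand, right hand) yields
four point correspondences, from which the linear map and offset

    X_A = R_BTA · X_BT + T_BTA

are solved in closed form: with difference matrices
D_A = [X2−X1 | X3−X1 | X4−X1] (A coords) and D_BT analogously,
R_BTA = D_A · D_BT⁻¹ and T_BTA = X1_A − R_BTA · X1_BT.  Four non-coplanar
points determine the map exactly; R_BTA is a general invertible 3×3 matrix
(no rigidity is imposed unless requested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JOINT_ORDER",
    "RegistrationSet",
    "FrameTransform",
    "DegenerateRegistrationError",
    "solve_calibration",
    "apply_transform",
    "invert_transform",
]

JOINT_ORDER = ("left_shoulder", "left_elbow", "left_hand", "right_hand")


class DegenerateRegistrationError(ValueError):
    """The four registered points are (near-)coplanar in the BT basis."""


@dataclass(frozen=True)
class RegistrationSet:
    """Four labeled joint correspondences (marker basis A, body basis BT)."""

    points_a: dict[str, np.ndarray]
    points_bt: dict[str, np.ndarray]

    def __post_init__(self):
        for name, pts in (("points_a", self.points_a),
                          ("points_bt", self.points_bt)):
            if set(pts) != set(JOINT_ORDER):
                raise ValueError(
                    f"{name} must contain exactly the joints {JOINT_ORDER}")
            object.__setattr__(self, name, {
                k: np.asarray(v, float).reshape(3) for k, v in pts.items()})

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(4, 3) arrays in canonical joint order: A coords, BT coords."""
        a = np.array([self.points_a[j] for j in JOINT_ORDER])
        bt = np.array([self.points_bt[j] for j in JOINT_ORDER])
        return a, bt

    def to_dict(self) -> dict:
        return {j: {"A": self.points_a[j].tolist(),
                    "BT": self.points_bt[j].tolist()} for j in JOINT_ORDER}

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationSet":
        return cls(points_a={j: np.array(d[j]["A"], float)
                             for j in JOINT_ORDER},
                   points_bt={j: np.array(d[j]["BT"], float)
                              for j in JOINT_ORDER})


@dataclass(frozen=True)
class FrameTransform:
    """Affine map from body-tracking coordinates into marker coordinates."""

    R: np.ndarray  # 3x3, invertible
    T: np.ndarray  # 3-vector

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, float).reshape(3, 3))
        object.__setattr__(self, "T", np.asarray(self.T, float).reshape(3))

    def __call__(self, x_bt: np.ndarray) -> np.ndarray:
        return apply_transform(self, x_bt)

    def to_json(self) -> str:
        return json.dumps({"R": [float(v) for v in self.R.flatten()],
                           "T": [float(v) for v in self.T]})

    @classmethod
    def from_json(cls, text: str) -> "FrameTransform":
        obj = json.loads(text)
        return cls(R=np.array(obj["R"], float).reshape(3, 3),
                   T=np.array(obj["T"], float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FrameTransform":
        with open(path) as fh:
            return cls.from_json(fh.read())


def solve_calibration(reg: RegistrationSet, cond_max: float = 1e6,
                      orthogonalize: bool = False) -> FrameTransform:
    """Closed-form solve of the frame transform from 4 correspondences.

    Parameters
    ----------
    reg : RegistrationSet
        Four non-coplanar labeled correspondences.
    cond_max : float
        Maximum accepted condition number of the BT difference matrix;
        beyond it the registration tetrahedron is treated as degenerate
        rather than silently amplifying noise.
    orthogonalize : bool
        Project the solved linear part onto the nearest rotation (polar
        projection) for users wanting a strictly rigid map.

    Raises
    ------
    DegenerateRegistrationError
        Coplanar/collinear BT points (singular or ill-conditioned).
    """
    a, bt = reg.stacked()
    d_a = (a[1:] - a[0]).T     # columns X2-X1, X3-X1, X4-X1 (A basis)
    d_bt = (bt[1:] - bt[0]).T  # same differences in the BT basis
    cond = np.linalg.cond(d_bt)
    if not np.isfinite(cond) or cond > cond_max:
        raise DegenerateRegistrationError(
            f"registration points are coplanar or near-coplanar in the "
            f"body-tracking basis (condition number {cond:.3g} > "
            f"{cond_max:.3g}); joints: {JOINT_ORDER}")
    R = d_a @ np.linalg.inv(d_bt)
    if orthogonalize:
        u, _, vt = np.linalg.svd(R)
        R = u @ np.diag([1.0, 1.0, np.linalg.det(u @ vt)]) @ vt
    T = a[0] - R @ bt[0]
    return FrameTransform(R=R, T=T)


def apply_transform(tf: FrameTransform, x_bt: np.ndarray) -> np.ndarray:
    """Map BT coordinates into the marker basis: R·x + T.

    Accepts a single 3-vector or an (n, 3) array.
    """
    x = np.asarray(x_bt, float)
    if x.ndim == 1:
        return tf.R @ x + tf.T
    return x @ tf.R.T + tf.T


def invert_transform(tf: FrameTransform) -> FrameTransform:
    """Inverse map (marker basis -> body-tracking basis)."""
    det = np.linalg.det(tf.R)
    if abs(det) < 1e-12:
        raise DegenerateRegistrationError("transform matrix is singular")
    R_inv = np.linalg.inv(tf.R)
    return FrameTransform(R=R_inv, T=-R_inv @ tf.T)
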