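"""Gridded atlas of pre-recorded ultrasound frames and display selection.

Frames were (conceptually) acquired on a forearm at the intersections of
two grids — 35 regularly spaced longitudinal positions from the inner
elbow to the wrist and 10 lateral positions from right to left — with a
40-frame back-to-front angular sweep over (−β, +β) at each point, in
B-mode and Doppler mode; Doppler additionally carries two 10 s clips at
fixed positions.

Selection maps a probe pose (marker basis) onto a frame key.  The
longitudinal rule is i = (l/L)·n, realised as the normative binning rule

    index(x; lo, hi, n) = clamp(floor((x−lo)/(hi−lo) · n) + 1, 1, n)

so the elbow (l = 0) shows the first image and the wrist (l = L) the
last; the same rule bins the sweep angle over (−β, +β) and the lateral
offset over (−half_width, +half_width).  Indices are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera_pose import Pose
from .frame_calibration import RegistrationSet

__all__ = [
    "BMODE",
    "DOPPLER",
    "AtlasGrid",
    "FrameKey",
    "ArmModel",
    "DopplerClip",
    "bin_index",
    "select_longitudinal",
    "select_sweep",
    "probe_to_frame_key",
    "arm_length_from_registration",
    "load_manifest",
    "save_manifest",
    "frame_path",
    "get_frame",
]

BMODE = "bmode"
DOPPLER = "doppler"


@dataclass(frozen=True)
class FrameKey:
    """Index into the atlas: mode, longitudinal u, lateral v, sweep a.

    u runs 1..n_long (1 = inner elbow, n_long = wrist), v runs 1..n_lat
    (1 = right), a runs 1..n_sweep (1 = −β end of the sweep).
    """

    mode: str
    u: int
    v: int
    a: int

    def as_tuple(self) -> tuple[str, int, int, int]:
        return (self.mode, self.u, self.v, self.a)


@dataclass(frozen=True)
class DopplerClip:
    """A timed Doppler clip attached to one frame key."""

    key: FrameKey
    path: str
    fps: float
    duration_s: float

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass(frozen=True)
class AtlasGrid:
    """Geometry of the acquisition grid and its sweep."""

    n_long: int = 35
    n_lat: int = 10
    n_sweep: int = 40
    beta_deg: float = 30.0
    modes: tuple[str, ...] = (BMODE, DOPPLER)
    clips: tuple[DopplerClip, ...] = field(default=())

    def __post_init__(self):
        if min(self.n_long, self.n_lat, self.n_sweep) < 1:
            raise ValueError("all grid counts must be >= 1")
        if self.beta_deg <= 0:
            raise ValueError("beta must be positive")
        for m in self.modes:
            if m not in (BMODE, DOPPLER):
                raise ValueError(f"unknown mode {m!r}")

    def validate_key(self, key: FrameKey) -> None:
        if key.mode not in self.modes:
            raise KeyError(f"mode {key.mode!r} not in atlas modes")
        if not (1 <= key.u <= self.n_long and 1 <= key.v <= self.n_lat
                and 1 <= key.a <= self.n_sweep):
            raise KeyError(
                f"frame key (u={key.u}, v={key.v}, a={key.a}) outside grid "
                f"{self.n_long}x{self.n_lat}x{self.n_sweep}")

    def keys(self, mode: str):
        for u in range(1, self.n_long + 1):
            for v in range(1, self.n_lat + 1):
                for a in range(1, self.n_sweep + 1):
                    yield FrameKey(mode=mode, u=u, v=v, a=a)


@dataclass(frozen=True)
class ArmModel:
    """User-specific forearm geometry in the marker basis.

    ``elbow`` and ``wrist`` anchor the longitudinal axis; ``L`` is their
    distance (user specific, measured at registration).  ``cross_axis``
    spans the right-to-left lateral direction, orthogonal to the axis;
    ``half_width`` is the lateral half-extent in metres.
    """

    elbow: np.ndarray
    wrist: np.ndarray
    cross_axis: np.ndarray
    half_width: float = 0.04

    def __post_init__(self):
        object.__setattr__(self, "elbow",
                           np.asarray(self.elbow, float).reshape(3))
        object.__setattr__(self, "wrist",
                           np.asarray(self.wrist, float).reshape(3))
        cross = np.asarray(self.cross_axis, float).reshape(3)
        axis = self.wrist - self.elbow
        L = np.linalg.norm(axis)
        if L <= 0:
            raise ValueError("elbow and wrist must be distinct (L > 0)")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        # project out any axial component, then normalize
        cross = cross - (cross @ axis) / (L * L) * axis
        norm = np.linalg.norm(cross)
        if norm < 1e-12:
            raise ValueError("cross_axis parallel to the arm axis")
        object.__setattr__(self, "cross_axis", cross / norm)

    @property
    def L(self) -> float:
        return float(np.linalg.norm(self.wrist - self.elbow))

    @property
    def axis(self) -> np.ndarray:
        """Unit elbow -> wrist direction."""
        return (self.wrist - self.elbow) / self.L

    @property
    def surface_normal(self) -> np.ndarray:
        """Unit normal to the arm surface (axis x cross_axis)."""
        n = np.cross(self.axis, self.cross_axis)
        return n / np.linalg.norm(n)

    def to_dict(self) -> dict:
        return {"elbow": self.elbow.tolist(), "wrist": self.wrist.tolist(),
                "cross_axis": self.cross_axis.tolist(),
                "half_width": self.half_width}

    @classmethod
    def from_dict(cls, d: dict) -> "ArmModel":
        return cls(elbow=d["elbow"], wrist=d["wrist"],
                   cross_axis=d["cross_axis"],
                   half_width=float(d.get("half_width", 0.04)))


def bin_index(x: float, lo: float, hi: float, n: int) -> int:
    """The normative binning rule: floor+1 with a closed final bin."""
    if hi <= lo:
        raise ValueError("binning range must have hi > lo")
    if n < 1:
        raise ValueError("n must be >= 1")
    frac = (x - lo) / (hi - lo)
    return int(np.clip(np.floor(frac * n) + 1, 1, n))


def select_longitudinal(l: float, L: float, n: int) -> int:
    """Longitudinal image index from elbow distance l: i = (l/L)·n, binned."""
    if L <= 0:
        raise ValueError("arm length L must be positive")
    return bin_index(max(l, 0.0), 0.0, L, n)


def select_sweep(angle_deg: float, beta_deg: float, n_sweep: int) -> int:
    """Sweep index from the probe-arm angle over (−β, +β); clamps outside."""
    if beta_deg <= 0:
        raise ValueError("beta must be positive")
    return bin_index(angle_deg, -beta_deg, beta_deg, n_sweep)


def select_lateral(c: float, half_width: float, n_lat: int) -> int:
    """Lateral index from the signed cross-axis offset c (metres)."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    return bin_index(c, -half_width, half_width, n_lat)


def probe_axis(pose: Pose) -> np.ndarray:
    """Probe pointing direction: the marker plane normal (marker +z)."""
    return pose.rotation @ np.array([0.0, 0.0, 1.0])


def sweep_angle_deg(pose: Pose, arm: ArmModel) -> float:
    """Signed probe-arm angle in the sweep (axis, normal) plane, degrees.

    Zero when the probe axis is anti-parallel to the arm surface normal
    (probe pressing straight down onto the arm); positive when tilted
    toward the wrist.
    """
    p = probe_axis(pose)
    along = float(p @ arm.axis)
    into = float(-p @ arm.surface_normal)
    if along == 0.0 and into == 0.0:
        return 0.0
    return float(np.degrees(np.arctan2(along, into)))


def probe_to_frame_key(pose: Pose, arm: ArmModel, grid: AtlasGrid,
                       mode: str = BMODE) -> FrameKey:
    """Compose the three selectors into the frame key to display."""
    if mode not in grid.modes:
        raise KeyError(f"mode {mode!r} not in atlas modes {grid.modes}")
    rel = pose.translation - arm.elbow
    l = max(float(rel @ arm.axis), 0.0)
    u = select_longitudinal(l, arm.L, grid.n_long)
    c = float(rel @ arm.cross_axis)
    v = select_lateral(c, arm.half_width, grid.n_lat)
    a = select_sweep(sweep_angle_deg(pose, arm), grid.beta_deg, grid.n_sweep)
    return FrameKey(mode=mode, u=u, v=v, a=a)


def arm_length_from_registration(reg: RegistrationSet) -> float:
    """User arm length L: elbow-to-hand distance in the marker basis."""
    elbow = reg.points_a.get("left_elbow")
    hand = reg.points_a.get("left_hand")
    if elbow is None or hand is None:
        raise ValueError("registration must contain left_elbow and left_hand")
    L = float(np.linalg.norm(hand - elbow))
    if L <= 0:
        raise ValueError("degenerate registration: elbow equals hand (L = 0)")
    return L


# -- manifest / frame I/O -------------------------------------------------

def frame_path(root, key: FrameKey) -> Path:
    """Canonical on-disk location ``<root>/<mode>/u{UU}_v{VV}_a{AA}.png``."""
    return (Path(root) / key.mode
            / f"u{key.u:02d}_v{key.v:02d}_a{key.a:02d}.png")


def save_manifest(grid: AtlasGrid, path) -> Path:
    path = Path(path)
    doc = {
        "n_long": grid.n_long, "n_lat": grid.n_lat, "n_sweep": grid.n_sweep,
        "beta_deg": grid.beta_deg, "modes": list(grid.modes),
        "clips": [{"key": list(c.key.as_tuple()), "path": c.path,
                   "fps": c.fps, "duration_s": c.duration_s}
                  for c in grid.clips],
    }
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_manifest(path) -> AtlasGrid:
    path = Path(path)
    doc = json.loads(path.read_text())
    clips = tuple(
        DopplerClip(key=FrameKey(mode=c["key"][0], u=int(c["key"][1]),
                                 v=int(c["key"][2]), a=int(c["key"][3])),
                    path=c["path"], fps=float(c["fps"]),
                    duration_s=float(c["duration_s"]))
        for c in doc.get("clips", []))
    return AtlasGrid(n_long=int(doc["n_long"]), n_lat=int(doc["n_lat"]),
                     n_sweep=int(doc["n_sweep"]),
                     beta_deg=float(doc["beta_deg"]),
                     modes=tuple(doc["modes"]), clips=clips)


def get_frame(root, grid: AtlasGrid, key: FrameKey) -> np.ndarray:
    """Load the unique image for a key; descriptive error when absent."""
    from imageio.v3 import imread

    grid.validate_key(key)
    path = frame_path(root, key)
    if not path.exists():
        raise FileNotFoundError(
            f"atlas frame missing for key (mode={key.mode}, u={key.u}, "
            f"v={key.v}, a={key.a}): expected {path}")
    return imread(path)


def clip_frame_index(clip: DopplerClip, elapsed_s: float) -> int:
    """Looping frame index into a Doppler clip at elapsed playback time."""
    if elapsed_s < 0:
        raise ValueError("elapsed time must be non-negative")
    return int(np.floor(elapsed_s * clip.fps)) % clip.n_frames
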