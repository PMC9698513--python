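"""Offline orchestration of a training session.

Two phases mirror the intended use of the system:

1. **Registration** — the learner holds the marker still at four joints
   in a fixed order (left shoulder, left elbow, left hand, right hand).
   Each dwell (marker detected and near-stationary for a minimum number
   of consecutive frames) yields one correspondence between the
   marker-tracking basis and the body-tracking basis; the four solve the
   frame transform and measure the user's arm length L.
2. **Training** — per frame, the probe marker is detected and its pose
   estimated; body keypoints are mapped through the transform; the arm
   model anchors follow the live transformed elbow/hand keypoints; the
   probe pose selects the atlas frame key to display.  Detection gaps
   are bridged by a hold-then-lost tracking policy (a marker occluded
   longer than ``hold_frames`` is reported lost rather than frozen).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .atlas import ArmModel, AtlasGrid, BMODE, FrameKey, frame_path, \
    probe_to_frame_key
from .camera_pose import CameraIntrinsics, MarkerGeometry, Pose, \
    PoseEstimationError, estimate_pose
from .detector import DetectorParams, detect
from .frame_calibration import FrameTransform, RegistrationSet, \
    apply_transform, solve_calibration, JOINT_ORDER
from .marker_codec import MarkerDictionary
from .synthetic import KeypointStream

__all__ = [
    "TrackingPolicy",
    "SessionConfig",
    "RegistrationError",
    "LogEntry",
    "run_registration",
    "run_session",
    "write_key_log",
]


class RegistrationError(RuntimeError):
    """A joint produced no qualifying dwell during registration."""


@dataclass(frozen=True)
class TrackingPolicy:
    """Hold-then-lost policy for detection gaps.

    hold_frames : maximum consecutive undetected frames over which the
        last frame key is re-emitted (status ``held``) before the probe
        is declared lost.  Default 10 frames, about 0.3 s at 30 fps —
        long enough to bridge single-frame decode misses, short enough
        not to mask true occlusion.
    """

    hold_frames: int = 10

    def __post_init__(self):
        if self.hold_frames < 0:
            raise ValueError("hold_frames must be >= 0")


@dataclass(frozen=True)
class SessionConfig:
    """Marker identity/size and registration dwell acceptance."""

    marker_id: int = 0
    side_length: float = 0.05
    dwell_min_frames: int = 15
    dwell_max_std: float = 0.003  # metres
    half_width: float = 0.04
    detector: DetectorParams = field(default_factory=DetectorParams)


@dataclass(frozen=True)
class LogEntry:
    """One per frame: tracked (fresh key), held (repeated), or lost."""

    t: float
    status: str  # tracked | held | lost
    key: FrameKey | None
    source_path: str | None = None

    def to_dict(self) -> dict:
        d = {"t": self.t, "status": self.status,
             "key": list(self.key.as_tuple()) if self.key else None}
        if self.source_path is not None:
            d["source_path"] = self.source_path
        return d


def _marker_positions(frames, dictionary, intrinsics, config
                      ) -> list[np.ndarray | None]:
    geom = MarkerGeometry(side_length=config.side_length)
    out: list[np.ndarray | None] = []
    for frame in frames:
        dets = [d for d in detect(frame, dictionary, config.detector)
                if d.id == config.marker_id]
        if not dets:
            out.append(None)
            continue
        try:
            pose, _ = estimate_pose(dets[0].corners, geom, intrinsics)
            out.append(pose.translation)
        except PoseEstimationError:
            out.append(None)
    return out


def _find_dwells(positions, min_frames: int, max_std: float
                 ) -> list[tuple[int, int]]:
    """Maximal stationary runs [start, stop) of detected positions."""
    dwells = []
    i, n = 0, len(positions)
    while i < n:
        if positions[i] is None:
            i += 1
            continue
        j = i + 1
        pts = [positions[i]]
        while j < n and positions[j] is not None:
            trial = pts + [positions[j]]
            arr = np.array(trial)
            if np.linalg.norm(arr.std(axis=0)) >= max_std:
                break
            pts = trial
            j += 1
        if len(pts) >= min_frames:
            dwells.append((i, i + len(pts)))
            i = i + len(pts)
        else:
            i += 1
    return dwells


def run_registration(frames, keypoints: KeypointStream,
                     dictionary: MarkerDictionary,
                     intrinsics: CameraIntrinsics,
                     config: SessionConfig = SessionConfig(),
                     cond_max: float = 1e6,
                     marker_positions=None
                     ) -> tuple[RegistrationSet, FrameTransform, ArmModel]:
    """Registration phase: four dwells -> transform + arm model.

    The four dwells are taken in time order and assigned to joints in
    the fixed order ``left_shoulder, left_elbow, left_hand, right_hand``.
    Per joint, the marker-basis position is the per-axis time median of
    the marker pose translation over the dwell, paired with the time
    median of that joint's keypoint coordinates over the same frames.

    ``marker_positions`` optionally supplies the per-frame marker-basis
    marker position directly (``None`` for undetected frames), bypassing
    the image pipeline — the injection point for any external marker
    tracker implementing the same contract.

    Raises
    ------
    RegistrationError
        If fewer than four qualifying dwells exist (names the first
        joint without one).
    DegenerateRegistrationError
        Propagated from the calibration solve for coplanar joints.
    """
    if marker_positions is None:
        positions = _marker_positions(frames, dictionary, intrinsics, config)
    else:
        positions = [None if p is None else np.asarray(p, float)
                     for p in marker_positions]
    dwells = _find_dwells(positions, config.dwell_min_frames,
                          config.dwell_max_std)
    if len(dwells) < 4:
        missing = JOINT_ORDER[len(dwells)]
        raise RegistrationError(
            f"registration incomplete: no qualifying dwell for joint "
            f"{missing!r} ({len(dwells)}/4 dwells found)")
    points_a, points_bt = {}, {}
    for joint, (start, stop) in zip(JOINT_ORDER, dwells[:4]):
        marker = np.median(np.array(positions[start:stop]), axis=0)
        kp = np.median(keypoints.positions[joint][start:stop], axis=0)
        points_a[joint] = marker
        points_bt[joint] = kp
    reg = RegistrationSet(points_a=points_a, points_bt=points_bt)
    transform = solve_calibration(reg, cond_max=cond_max)
    arm = _arm_model_from_points(points_a["left_shoulder"],
                                 points_a["left_elbow"],
                                 points_a["left_hand"], config.half_width)
    return reg, transform, arm


def _arm_model_from_points(shoulder, elbow, hand, half_width) -> ArmModel:
    """Arm model with the cross-axis in the shoulder-elbow-hand plane.

    The surface normal is oriented toward the camera (the marker basis is
    the camera frame, so the scanned surface faces -z); a probe pressing
    straight onto the arm then reads a sweep angle of zero.
    """
    axis = np.asarray(hand, float) - np.asarray(elbow, float)
    toward_shoulder = np.asarray(shoulder, float) - np.asarray(elbow, float)
    normal = np.cross(axis, toward_shoulder)
    if np.linalg.norm(normal) < 1e-9:
        normal = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(normal) < 1e-9:
            normal = np.cross(axis, [0.0, 1.0, 0.0])
    cross_axis = np.cross(normal, axis)
    arm = ArmModel(elbow=elbow, wrist=hand, cross_axis=cross_axis,
                   half_width=half_width)
    if arm.surface_normal[2] > 0:  # facing away from the camera: flip
        arm = ArmModel(elbow=elbow, wrist=hand, cross_axis=-cross_axis,
                       half_width=half_width)
    return arm


def run_session(frames, keypoints: KeypointStream,
                transform: FrameTransform, arm: ArmModel, grid: AtlasGrid,
                dictionary: MarkerDictionary, intrinsics: CameraIntrinsics,
                policy: TrackingPolicy = TrackingPolicy(),
                config: SessionConfig = SessionConfig(),
                mode: str = BMODE, atlas_root=None, fps: float = 30.0,
                follow_keypoints: bool = True) -> list[LogEntry]:
    """Training phase: one log entry per frame (tracked, held, or lost).

    With ``follow_keypoints`` the arm anchors track the live transformed
    elbow/hand keypoints (the virtual arm follows the learner); without
    it the frozen registration-time arm model is used.
    """
    geom = MarkerGeometry(side_length=config.side_length)
    log: list[LogEntry] = []
    last_key: FrameKey | None = None
    gap = 0
    for f, frame in enumerate(frames):
        t = f / fps
        arm_now = arm
        if follow_keypoints and f < keypoints.n_frames:
            kp = keypoints.at(f)
            elbow_a = apply_transform(transform, kp["left_elbow"])
            hand_a = apply_transform(transform, kp["left_hand"])
            shoulder_a = apply_transform(transform, kp["left_shoulder"])
            try:
                arm_now = _arm_model_from_points(
                    shoulder_a, elbow_a, hand_a, config.half_width)
            except ValueError:
                arm_now = arm
        dets = [d for d in detect(frame, dictionary, config.detector)
                if d.id == config.marker_id]
        pose: Pose | None = None
        if dets:
            try:
                pose, _ = estimate_pose(dets[0].corners, geom, intrinsics)
            except PoseEstimationError:
                pose = None
        if pose is not None:
            key = probe_to_frame_key(pose, arm_now, grid, mode)
            grid.validate_key(key)
            src = str(frame_path(atlas_root, key)) if atlas_root else None
            log.append(LogEntry(t=t, status="tracked", key=key,
                                source_path=src))
            last_key = key
            gap = 0
        else:
            gap += 1
            if last_key is not None and gap <= policy.hold_frames:
                src = (str(frame_path(atlas_root, last_key))
                       if atlas_root else None)
                log.append(LogEntry(t=t, status="held", key=last_key,
                                    source_path=src))
            else:
                log.append(LogEntry(t=t, status="lost", key=None))
    return log


def write_key_log(log: list[LogEntry], path) -> None:
    """Serialize a key log as JSON lines."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry.to_dict()) + "\n")
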