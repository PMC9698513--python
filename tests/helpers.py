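"""Shared scene builders for session-level and acceptance tests."""

import numpy as np

from arustrain.frame_calibration import JOINT_ORDER
from arustrain.synthetic import (KeypointStream, MarkerTrack, SceneScript,
                                 make_pose, render_scene)

# ground-truth relation between the two bases: X_A = G_R · X_BT + G_T
G_R = np.array([[0.9, 0.1, 0.0], [0.0, 1.05, -0.1], [0.05, 0.0, 1.0]])
G_T = np.array([0.02, -0.05, 0.1])

# joint anchor points in the marker (camera) basis, metres
JOINT_POINTS_A = {
    "left_shoulder": np.array([-0.10, -0.10, 0.45]),
    "left_elbow": np.array([-0.08, 0.02, 0.50]),
    "left_hand": np.array([0.10, 0.02, 0.50]),
    "right_hand": np.array([0.05, -0.08, 0.58]),
}


def joint_points_bt():
    inv = np.linalg.inv(G_R)
    return {j: inv @ (p - G_T) for j, p in JOINT_POINTS_A.items()}


def registration_poses(dwell=18, travel=6):
    """Marker pose track dwelling at each joint in canonical order."""
    poses = []
    order = list(JOINT_ORDER)
    for k, joint in enumerate(order):
        p = JOINT_POINTS_A[joint]
        poses += [make_pose(tilt_deg=10, position=p)] * dwell
        if k < 3:
            q = JOINT_POINTS_A[order[k + 1]]
            poses += [make_pose(tilt_deg=10, position=(1 - s) * p + s * q)
                      for s in np.linspace(0.15, 0.85, travel)]
    return poses


def static_keypoint_stream(n_frames, sigma=0.0, seed=0):
    """Keypoints pinned at the BT-basis joint anchors (optionally noisy)."""
    rng = np.random.default_rng(seed)
    pts_bt = joint_points_bt()
    positions = {}
    for j in JOINT_ORDER:
        track = np.tile(pts_bt[j], (n_frames, 1))
        if sigma > 0:
            track = track + rng.normal(0, sigma, track.shape)
        positions[j] = track
    return KeypointStream(positions=positions,
                          noise_free={j: np.tile(pts_bt[j], (n_frames, 1))
                                      for j in JOINT_ORDER},
                          fps=30.0, sigma=sigma, seed=seed)


def sweep_poses(n_frames, tilt_deg=0.0):
    """Straight-line probe path from the elbow anchor to the hand anchor."""
    elbow = JOINT_POINTS_A["left_elbow"]
    wrist = JOINT_POINTS_A["left_hand"]
    return [make_pose(tilt_deg=tilt_deg,
                      position=(1 - s) * elbow + s * wrist)
            for s in np.linspace(0, 1, n_frames)]


def render_marker_script(intrinsics, dictionary, poses, marker_id=0,
                         side_length=0.05, seed=0, occlusions=()):
    script = SceneScript(intrinsics=intrinsics, image_size=(640, 480),
                         tracks=(MarkerTrack(marker_id, side_length,
                                             tuple(poses)),),
                         n_frames=len(poses), background="flat", seed=seed,
                         occlusions=tuple(occlusions))
    return render_scene(script, dictionary)
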