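"""Self-validation harness: recomputes the engine's headline quantities.

Each function runs one validation study from scratch on synthetic inputs
and returns plain numbers: the atlas protocol constants, the exactness of
the closed-form calibration against a stacked linear-system oracle, the
detector/pose closure on a rendered corpus, the totality of the
frame-selection binning rule, end-to-end session recovery, and the
monotone growth of errors with injected noise.  Problem sizes are
arguments so studies can be scaled.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .atlas import AtlasGrid, load_manifest, probe_to_frame_key, \
    select_longitudinal
from .camera_pose import CameraIntrinsics, MarkerGeometry, estimate_pose, \
    project
from .detector import detect
from .frame_calibration import (JOINT_ORDER, DegenerateRegistrationError,
                                RegistrationSet, apply_transform,
                                solve_calibration)
from .marker_codec import build_dictionary
from .session import SessionConfig, TrackingPolicy, run_registration, \
    run_session
from .synthetic import (KeypointStream, MarkerTrack, Occlusion, SceneScript,
                        generate_atlas, make_pose, render_scene)

DEFAULT_INTRINSICS = CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0,
                                      cy=240.0, image_size=(640, 480))

# ground-truth basis relation used by the session studies
GROUND_R = np.array([[0.9, 0.1, 0.0], [0.0, 1.05, -0.1], [0.05, 0.0, 1.0]])
GROUND_T = np.array([0.02, -0.05, 0.1])
JOINT_POINTS_A = {
    "left_shoulder": np.array([-0.10, -0.10, 0.45]),
    "left_elbow": np.array([-0.08, 0.02, 0.50]),
    "left_hand": np.array([0.10, 0.02, 0.50]),
    "right_hand": np.array([0.05, -0.08, 0.58]),
}


def atlas_protocol_constants(seed: int = 0, out_dir=None) -> dict:
    """Generate the default atlas and read its protocol constants back."""
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return atlas_protocol_constants(seed, tmp)
    grid = AtlasGrid()
    manifest = generate_atlas(grid, seed=seed, out_dir=out_dir)
    restored = load_manifest(manifest)
    root = Path(out_dir)
    counts = {mode: len(list((root / mode).glob("*.png")))
              for mode in restored.modes}
    return {
        "n_long": restored.n_long,
        "n_lat": restored.n_lat,
        "n_sweep": restored.n_sweep,
        "n_doppler_clips": len(restored.clips),
        "clip_duration_s": (restored.clips[0].duration_s
                            if restored.clips else 0.0),
        "frames_per_mode": counts,
        "complete": all(c == restored.n_long * restored.n_lat
                        * restored.n_sweep for c in counts.values()),
    }


def _lstsq_oracle(pts_bt, pts_a):
    A = np.zeros((12, 12))
    b = np.zeros(12)
    for k in range(4):
        for row in range(3):
            A[3 * k + row, 3 * row:3 * row + 3] = pts_bt[k]
            A[3 * k + row, 9 + row] = 1.0
            b[3 * k + row] = pts_a[k][row]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:9].reshape(3, 3), sol[9:]


def calibration_exactness(n_trials: int = 200, seed: int = 0) -> dict:
    """Recover seeded ground-truth affine maps from noise-free points."""
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    max_oracle_dev = 0.0
    done = 0
    while done < n_trials:
        A = rng.normal(size=(3, 3))
        if abs(np.linalg.det(A)) < 0.1:
            continue
        t = rng.normal(size=3)
        pts = rng.normal(size=(4, 3))
        targets = pts @ A.T + t
        reg = RegistrationSet(
            points_a={j: q for j, q in zip(JOINT_ORDER, targets)},
            points_bt={j: q for j, q in zip(JOINT_ORDER, pts)})
        try:
            tf = solve_calibration(reg)
        except DegenerateRegistrationError:
            continue
        scale = max(np.abs(A).max(), np.abs(t).max(), 1.0)
        max_rel = max(max_rel,
                      float(np.abs(tf.R - A).max() / scale),
                      float(np.abs(tf.T - t).max() / scale))
        R_o, t_o = _lstsq_oracle(pts, targets)
        max_oracle_dev = max(max_oracle_dev,
                             float(np.abs(tf.R - R_o).max()),
                             float(np.abs(tf.T - t_o).max()))
        done += 1
    flat = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    try:
        solve_calibration(RegistrationSet(
            points_a={j: q for j, q in zip(JOINT_ORDER, flat)},
            points_bt={j: q for j, q in zip(JOINT_ORDER, flat)}))
        coplanar_rejected = False
    except DegenerateRegistrationError:
        coplanar_rejected = True
    return {"n_trials": done, "max_rel_error": max_rel,
            "max_oracle_deviation": max_oracle_dev,
            "coplanar_rejected": coplanar_rejected}


def detector_pose_closure(n_frames: int = 200, seed: int = 0,
                          intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
                          ) -> dict:
    """Detection rate / corner RMS on rendered frames; pose closure on
    the same poses from noise-free corner projections.

    Corpus: one marker per frame, tilt <= 45 deg, side >= 80 px, flat
    background, no occlusion, no noise.
    """
    rng = np.random.default_rng(seed)
    dictionary = build_dictionary(50, 4, 3, seed=0)
    geom = MarkerGeometry(side_length=0.05)
    detected = 0
    sq_err = 0.0
    n_corners = 0
    rot_err_max = 0.0
    trans_err_pct_max = 0.0
    rmse_max = 0.0
    for k in range(n_frames):
        marker_id = int(rng.integers(0, 50))
        pose = make_pose(tilt_deg=float(rng.uniform(0, 45)),
                         spin_deg=float(rng.uniform(0, 360)),
                         azimuth_deg=float(rng.uniform(0, 360)),
                         position=(float(rng.uniform(-0.05, 0.05)),
                                   float(rng.uniform(-0.04, 0.04)),
                                   float(rng.uniform(0.28, 0.36))))
        script = SceneScript(intrinsics=intrinsics, image_size=(640, 480),
                             tracks=(MarkerTrack(marker_id, 0.05, (pose,)),),
                             n_frames=1, background="flat", seed=seed + k)
        frames, truths = render_scene(script, dictionary)
        dets = [d for d in detect(frames[0], dictionary)
                if d.id == marker_id]
        if dets:
            detected += 1
            err = np.linalg.norm(
                dets[0].corners - truths[0].corners[marker_id], axis=1)
            sq_err += float((err ** 2).sum())
            n_corners += 4
        # pose closure on the exact (noise-free) corner projections
        obs = project(geom.corners, pose, intrinsics)
        est, rmse = estimate_pose(obs, geom, intrinsics)
        rot_err = np.degrees(Rotation.from_matrix(
            est.rotation @ pose.rotation.T).magnitude())
        trans_err = np.linalg.norm(est.translation - pose.translation)
        rot_err_max = max(rot_err_max, float(rot_err))
        trans_err_pct_max = max(trans_err_pct_max,
                                float(100 * trans_err / pose.translation[2]))
        rmse_max = max(rmse_max, float(rmse))
    return {
        "n_frames": n_frames,
        "detection_rate_pct": 100.0 * detected / n_frames,
        "corner_rms_px": float(np.sqrt(sq_err / n_corners))
        if n_corners else float("nan"),
        "pose_rot_err_deg_max": rot_err_max,
        "pose_trans_err_pct_max": trans_err_pct_max,
        "pose_rmse_px_max": rmse_max,
    }


def selection_totality(max_n: int = 64, samples_per_bin: int = 20) -> dict:
    """Exhaustive bin audit of the longitudinal selection rule."""
    all_ok = True
    for n in range(1, max_n + 1):
        ls = (np.arange(samples_per_bin * n) + 0.5) / (samples_per_bin * n)
        idx = np.array([select_longitudinal(l, 1.0, n) for l in ls])
        ok = (np.all(np.diff(idx) >= 0)
              and set(idx) == set(range(1, n + 1))
              and np.all(np.bincount(idx)[1:] == samples_per_bin)
              and select_longitudinal(0.0, 1.0, n) == 1
              and select_longitudinal(1.0, 1.0, n) == n)
        all_ok = all_ok and bool(ok)
    return {"max_n": max_n, "all_bins_ok": all_ok}


def _static_stream(n_frames: int) -> KeypointStream:
    inv = np.linalg.inv(GROUND_R)
    pts_bt = {j: inv @ (p - GROUND_T) for j, p in JOINT_POINTS_A.items()}
    positions = {j: np.tile(pts_bt[j], (n_frames, 1)) for j in JOINT_ORDER}
    return KeypointStream(positions=positions, noise_free=positions,
                          fps=30.0, sigma=0.0, seed=0)


def session_recovery(n_sweep_frames: int = 200, seed: int = 0,
                     hold_frames: int = 5,
                     intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
                     ) -> dict:
    """Full offline session: registration, sweep recovery, occlusions."""
    dictionary = build_dictionary(50, 4, 3, seed=0)
    config = SessionConfig()
    grid = AtlasGrid()
    # registration scene: dwell at the four joints in order
    reg_poses = []
    order = list(JOINT_ORDER)
    for k, joint in enumerate(order):
        p = JOINT_POINTS_A[joint]
        reg_poses += [make_pose(tilt_deg=10, position=p)] * 18
        if k < 3:
            q = JOINT_POINTS_A[order[k + 1]]
            reg_poses += [make_pose(tilt_deg=10,
                                    position=(1 - s) * p + s * q)
                          for s in np.linspace(0.15, 0.85, 6)]
    script = SceneScript(intrinsics=intrinsics, image_size=(640, 480),
                         tracks=(MarkerTrack(0, 0.05, tuple(reg_poses)),),
                         n_frames=len(reg_poses), seed=seed)
    frames, _ = render_scene(script, dictionary)
    stream = _static_stream(len(reg_poses))
    _, tf, arm = run_registration(frames, stream, dictionary, intrinsics,
                                  config)
    # elbow -> wrist sweep
    elbow = JOINT_POINTS_A["left_elbow"]
    wrist = JOINT_POINTS_A["left_hand"]
    sweep = [make_pose(tilt_deg=0, position=(1 - s) * elbow + s * wrist)
             for s in np.linspace(0, 1, n_sweep_frames)]
    script2 = SceneScript(intrinsics=intrinsics, image_size=(640, 480),
                          tracks=(MarkerTrack(0, 0.05, tuple(sweep)),),
                          n_frames=n_sweep_frames, seed=seed + 1)
    frames2, truths2 = render_scene(script2, dictionary)
    stream2 = _static_stream(n_sweep_frames)
    log = run_session(frames2, stream2, tf, arm, grid, dictionary,
                      intrinsics, config=config)
    us = [e.key.u for e in log if e.key is not None]
    agree = sum(
        1 for e, truth in zip(log, truths2)
        if e.key == probe_to_frame_key(truth.poses[0], arm, grid))
    # occlusion policy: short and long gaps against hold_frames
    policy = TrackingPolicy(hold_frames=hold_frames)
    occ_stats = {}
    for occ_len in (hold_frames - 2, 2 * hold_frames):
        n_occ = 40
        occ_sweep = sweep[:n_occ]
        script3 = SceneScript(
            intrinsics=intrinsics, image_size=(640, 480),
            tracks=(MarkerTrack(0, 0.05, tuple(occ_sweep)),),
            n_frames=n_occ, seed=seed + 2,
            occlusions=(Occlusion(start=20, stop=20 + occ_len,
                                  rect=(0, 0, 640, 480)),))
        frames3, _ = render_scene(script3, dictionary)
        log3 = run_session(frames3, _static_stream(n_occ), tf, arm, grid,
                           dictionary, intrinsics, policy=policy,
                           config=config)
        gap = log3[20:20 + occ_len]
        occ_stats[occ_len] = {
            "held": sum(1 for e in gap if e.status == "held"),
            "lost": sum(1 for e in gap if e.status == "lost"),
        }
    return {
        "n_sweep_frames": n_sweep_frames,
        "agreement_pct": 100.0 * agree / n_sweep_frames,
        "u_first": us[0], "u_last": us[-1],
        "u_non_decreasing": bool(all(b >= a for a, b in zip(us, us[1:]))),
        "u_coverage": len(set(us)),
        "hold_frames": hold_frames,
        "occlusion": occ_stats,
        "log_length_ok": len(log) == n_sweep_frames,
    }


def noise_monotonicity(n_seeds: int = 50, seed: int = 0,
                       intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
                       ) -> dict:
    """Median errors must grow with injected Gaussian noise sigma."""
    rng = np.random.default_rng(seed)
    # registration transfer error vs keypoint noise (exact marker positions)
    inv = np.linalg.inv(GROUND_R)
    pts_bt = {j: inv @ (p - GROUND_T) for j, p in JOINT_POINTS_A.items()}
    held_bt = rng.normal(0, 0.2, size=(30, 3))
    held_a = held_bt @ GROUND_R.T + GROUND_T
    reg_sigmas = (0.001, 0.005, 0.02)
    reg_medians = []
    for sigma in reg_sigmas:
        errs = []
        for s in range(n_seeds):
            srng = np.random.default_rng(seed * 1000 + s)
            reg = RegistrationSet(
                points_a={j: JOINT_POINTS_A[j] for j in JOINT_ORDER},
                points_bt={j: pts_bt[j] + srng.normal(0, sigma, 3)
                           for j in JOINT_ORDER})
            try:
                tf = solve_calibration(reg)
            except DegenerateRegistrationError:
                continue
            errs.append(float(np.median(np.linalg.norm(
                apply_transform(tf, held_bt) - held_a, axis=1))))
        reg_medians.append(float(np.median(errs)))
    # pose translation error vs corner noise
    geom = MarkerGeometry(side_length=0.05)
    pose_sigmas = (0.1, 0.5, 1.0)
    truths = [make_pose(tilt_deg=float(rng.uniform(5, 50)),
                        spin_deg=float(rng.uniform(0, 360)),
                        azimuth_deg=float(rng.uniform(0, 360)),
                        position=(float(rng.uniform(-0.05, 0.05)),
                                  float(rng.uniform(-0.05, 0.05)),
                                  float(rng.uniform(0.4, 0.8))))
              for _ in range(n_seeds)]
    pose_medians = []
    for sigma in pose_sigmas:
        errs = []
        for s, truth in enumerate(truths):
            srng = np.random.default_rng(seed * 2000 + s)
            obs = project(geom.corners, truth, intrinsics) \
                + srng.normal(0, sigma, (4, 2))
            est, _ = estimate_pose(obs, geom, intrinsics)
            errs.append(float(np.linalg.norm(est.translation
                                             - truth.translation)))
        pose_medians.append(float(np.median(errs)))
    return {
        "n_seeds": n_seeds,
        "registration_sigmas_m": list(reg_sigmas),
        "registration_median_errors_m": reg_medians,
        "registration_monotone": bool(reg_medians[0] < reg_medians[1]
                                      < reg_medians[2]),
        "pose_sigmas_px": list(pose_sigmas),
        "pose_median_errors_m": pose_medians,
        "pose_monotone": bool(pose_medians[0] < pose_medians[1]
                              < pose_medians[2]),
    }
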