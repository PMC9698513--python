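"""Registration procedure, tracking policy, and session key logs."""

import numpy as np
import pytest

import helpers
from arustrain.atlas import AtlasGrid, probe_to_frame_key
from arustrain.frame_calibration import (JOINT_ORDER,
                                         DegenerateRegistrationError)
from arustrain.session import (RegistrationError, SessionConfig,
                               TrackingPolicy, run_registration, run_session)
from arustrain.synthetic import Occlusion, make_pose


@pytest.fixture(scope="module")
def registration_corpus(dictionary, intrinsics):
    poses = helpers.registration_poses()
    frames, _ = helpers.render_marker_script(intrinsics, dictionary, poses,
                                             seed=3)
    stream = helpers.static_keypoint_stream(len(poses))
    return poses, frames, stream


@pytest.fixture(scope="module")
def solved_registration(registration_corpus, dictionary, intrinsics):
    _, frames, stream = registration_corpus
    return run_registration(frames, stream, dictionary, intrinsics)


@pytest.fixture(scope="module")
def sweep_corpus(dictionary, intrinsics):
    poses = helpers.sweep_poses(80)
    frames, truths = helpers.render_marker_script(intrinsics, dictionary,
                                                  poses, seed=4)
    stream = helpers.static_keypoint_stream(len(poses))
    return poses, frames, truths, stream


class TestRegistration:
    def test_exact_recovery_from_ground_truth_positions(
            self, registration_corpus, dictionary, intrinsics):
        """Bypassing the image pipeline, recovery is exact (<= 1e-6)."""
        poses, _, stream = registration_corpus
        exact = [p.translation for p in poses]
        _, tf, _ = run_registration(None, stream, dictionary, intrinsics,
                                    marker_positions=exact)
        assert np.abs(tf.R - helpers.G_R).max() <= 1e-6
        assert np.abs(tf.T - helpers.G_T).max() <= 1e-6

    def test_recovery_through_rendered_frames(self, solved_registration):
        """Full image pipeline: sub-millimetre transform recovery."""
        _, tf, arm = solved_registration
        assert np.abs(tf.R - helpers.G_R).max() <= 5e-3
        assert np.abs(tf.T - helpers.G_T).max() <= 2e-3
        want_L = np.linalg.norm(helpers.JOINT_POINTS_A["left_hand"]
                                - helpers.JOINT_POINTS_A["left_elbow"])
        assert arm.L == pytest.approx(want_L, abs=1e-3)

    def test_registration_set_round_trip(self, solved_registration):
        from arustrain.frame_calibration import RegistrationSet
        reg, _, _ = solved_registration
        restored = RegistrationSet.from_dict(reg.to_dict())
        for j in JOINT_ORDER:
            assert np.allclose(restored.points_a[j], reg.points_a[j])

    def test_missing_dwell_names_joint(self, dictionary, intrinsics):
        # only two dwells: third joint (left_hand) must be named
        poses = []
        for joint in JOINT_ORDER[:2]:
            p = helpers.JOINT_POINTS_A[joint]
            poses += [make_pose(tilt_deg=10, position=p)] * 18
        stream = helpers.static_keypoint_stream(len(poses))
        exact = [p.translation for p in poses]
        with pytest.raises(RegistrationError, match="left_hand"):
            run_registration(None, stream, dictionary, intrinsics,
                             marker_positions=exact)

    def test_coplanar_joints_degenerate(self, dictionary, intrinsics):
        flat = {
            "left_shoulder": np.array([-0.1, 0.0, 0.5]),
            "left_elbow": np.array([0.0, 0.0, 0.5]),
            "left_hand": np.array([0.1, 0.0, 0.5]),
            "right_hand": np.array([0.0, 0.1, 0.5]),
        }
        poses = []
        for joint in JOINT_ORDER:
            poses += [make_pose(tilt_deg=0, position=flat[joint])] * 18
        exact = [p.translation for p in poses]
        inv = np.linalg.inv(helpers.G_R)
        from arustrain.synthetic import KeypointStream
        positions = {j: np.tile(inv @ (flat[j] - helpers.G_T),
                                (len(poses), 1)) for j in JOINT_ORDER}
        stream = KeypointStream(positions=positions, noise_free=positions,
                                fps=30, sigma=0, seed=0)
        with pytest.raises(DegenerateRegistrationError):
            run_registration(None, stream, dictionary, intrinsics,
                             marker_positions=exact)

    def test_noise_monotone_transfer_error(self, dictionary, intrinsics):
        """Median held-out transfer error grows with keypoint noise."""
        poses = helpers.registration_poses()
        exact = [p.translation for p in poses]
        rng = np.random.default_rng(17)
        held_out_bt = rng.normal(0, 0.2, size=(30, 3))
        held_out_a = held_out_bt @ helpers.G_R.T + helpers.G_T
        medians = []
        for sigma in (0.001, 0.005, 0.02):
            errs = []
            for seed in range(25):
                stream = helpers.static_keypoint_stream(
                    len(poses), sigma=sigma, seed=seed)
                try:
                    _, tf, _ = run_registration(
                        None, stream, dictionary, intrinsics,
                        marker_positions=exact)
                except DegenerateRegistrationError:
                    continue
                from arustrain.frame_calibration import apply_transform
                errs.append(np.median(np.linalg.norm(
                    apply_transform(tf, held_out_bt) - held_out_a, axis=1)))
            medians.append(np.median(errs))
        assert medians[0] < medians[1] < medians[2]


class TestSession:
    def test_log_length_equals_frame_count(self, sweep_corpus,
                                           solved_registration,
                                           dictionary, intrinsics):
        _, frames, _, stream = sweep_corpus
        _, tf, arm = solved_registration
        log = run_session(frames, stream, tf, arm, AtlasGrid(), dictionary,
                          intrinsics)
        assert len(log) == len(frames)

    def test_sweep_u_non_decreasing_and_covering(self, sweep_corpus,
                                                 solved_registration,
                                                 dictionary, intrinsics):
        _, frames, _, stream = sweep_corpus
        _, tf, arm = solved_registration
        log = run_session(frames, stream, tf, arm, AtlasGrid(), dictionary,
                          intrinsics)
        us = [e.key.u for e in log if e.key is not None]
        assert us[0] == 1 and us[-1] == 35
        assert all(b >= a for a, b in zip(us, us[1:]))

    def test_log_matches_ground_truth_geometry(self, sweep_corpus,
                                               solved_registration,
                                               dictionary, intrinsics):
        poses, frames, truths, stream = sweep_corpus
        _, tf, arm = solved_registration
        grid = AtlasGrid()
        log = run_session(frames, stream, tf, arm, grid, dictionary,
                          intrinsics)
        agree = sum(
            1 for entry, truth in zip(log, truths)
            if entry.key == probe_to_frame_key(truth.poses[0], arm, grid))
        assert agree / len(log) >= 0.99

    @pytest.mark.parametrize("occ_len,hold,want_held,want_lost",
                             [(3, 5, 3, 0), (10, 5, 5, 5)])
    def test_occlusion_policy_hold_then_lost(self, occ_len, hold, want_held,
                                             want_lost, solved_registration,
                                             dictionary, intrinsics):
        poses = helpers.sweep_poses(40)
        occ = Occlusion(start=20, stop=20 + occ_len, rect=(0, 0, 640, 480))
        frames, _ = helpers.render_marker_script(
            intrinsics, dictionary, poses, seed=4, occlusions=(occ,))
        stream = helpers.static_keypoint_stream(len(poses))
        _, tf, arm = solved_registration
        log = run_session(frames, stream, tf, arm, AtlasGrid(), dictionary,
                          intrinsics, policy=TrackingPolicy(hold_frames=hold))
        gap = log[20:20 + occ_len]
        assert sum(1 for e in gap if e.status == "held") == want_held
        assert sum(1 for e in gap if e.status == "lost") == want_lost
        # held entries repeat the last tracked key
        for e in gap:
            if e.status == "held":
                assert e.key == log[19].key
        assert log[20 + occ_len].status == "tracked"

    def test_replay_deterministic(self, sweep_corpus, solved_registration,
                                  dictionary, intrinsics):
        _, frames, _, stream = sweep_corpus
        _, tf, arm = solved_registration
        log1 = run_session(frames[:10], stream, tf, arm, AtlasGrid(),
                           dictionary, intrinsics)
        log2 = run_session(frames[:10], stream, tf, arm, AtlasGrid(),
                           dictionary, intrinsics)
        assert [e.to_dict() for e in log1] == [e.to_dict() for e in log2]

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            TrackingPolicy(hold_frames=-1)
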