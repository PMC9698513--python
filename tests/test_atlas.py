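"""Frame-key binning rules, probe-to-key geometry, manifest I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arustrain.atlas import (ArmModel, AtlasGrid, BMODE, DOPPLER, FrameKey,
                             arm_length_from_registration, bin_index,
                             clip_frame_index, frame_path, get_frame,
                             load_manifest, probe_to_frame_key, save_manifest,
                             select_lateral, select_longitudinal,
                             select_sweep, sweep_angle_deg)
from arustrain.frame_calibration import JOINT_ORDER, RegistrationSet
from arustrain.synthetic import generate_atlas, make_pose


@pytest.fixture
def arm():
    return ArmModel(elbow=[0.0, 0.0, 0.5], wrist=[0.3, 0.0, 0.5],
                    cross_axis=[0.0, -1.0, 0.0], half_width=0.04)


class TestSelectors:
    def test_elbow_maps_to_first_image(self):
        assert select_longitudinal(0.0, 0.3, 35) == 1

    def test_wrist_clamps_to_last_image(self):
        assert select_longitudinal(0.3, 0.3, 35) == 35
        assert select_longitudinal(0.5, 0.3, 35) == 35

    def test_midpoint_even_count(self):
        # l/L = 0.5 with n = 34: 0.5*34 = 17 -> floor + 1 = 18
        assert select_longitudinal(0.15, 0.3, 34) == 18

    def test_nonpositive_length_errors(self):
        with pytest.raises(ValueError):
            select_longitudinal(0.1, 0.0, 35)

    def test_sweep_endpoints_and_centre(self):
        assert select_sweep(-30.0, 30.0, 40) == 1
        assert select_sweep(30.0, 30.0, 40) == 40
        assert select_sweep(0.0, 30.0, 40) == 21
        assert select_sweep(-90.0, 30.0, 40) == 1
        assert select_sweep(90.0, 30.0, 40) == 40

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 13, 21, 34, 35, 55, 64])
    def test_bin_totality_contiguous_equal_width(self, n):
        """n contiguous equal-width preimage intervals; closed final bin."""
        L = 1.0
        # sample bin interiors (half-step offset keeps floating-point
        # round-off away from the analytic bin edges)
        ls = (np.arange(20 * n) + 0.5) / (20 * n)
        idx = np.array([select_longitudinal(l, L, n) for l in ls])
        assert np.all(np.diff(idx) >= 0)
        assert set(idx) == set(range(1, n + 1))
        counts = np.bincount(idx)[1:]
        assert np.all(counts == 20)  # equal-width contiguous preimages
        assert select_longitudinal(0.0, L, n) == 1
        assert select_longitudinal(L, L, n) == n  # closed final bin

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0,
                                                          max_value=1),
           st.integers(min_value=1, max_value=64))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_l_property(self, l1, l2, n):
        lo, hi = sorted((l1, l2))
        assert select_longitudinal(lo, 1.0, n) <= \
            select_longitudinal(hi, 1.0, n)

    def test_bin_index_validation(self):
        with pytest.raises(ValueError):
            bin_index(0.5, 1.0, 0.0, 4)
        with pytest.raises(ValueError):
            bin_index(0.5, 0.0, 1.0, 0)


class TestProbeToFrameKey:
    def test_probe_at_elbow_reference(self, arm):
        grid = AtlasGrid()
        pose = make_pose(tilt_deg=0, position=arm.elbow)
        key = probe_to_frame_key(pose, arm, grid)
        assert key.u == 1
        assert key.v == 6  # centre bin of 10 under floor+1
        assert key.a == 21  # centre bin of 40

    def test_probe_at_wrist(self, arm):
        grid = AtlasGrid()
        pose = make_pose(tilt_deg=0, position=arm.wrist)
        assert probe_to_frame_key(pose, arm, grid).u == grid.n_long

    def test_sweep_angle_sign_convention(self, arm):
        # tilt toward the wrist (+axis) must increase the sweep index
        pose_fwd = make_pose(tilt_deg=20, azimuth_deg=90,
                             position=arm.elbow + 0.1 * arm.axis)
        pose_back = make_pose(tilt_deg=-20, azimuth_deg=90,
                              position=arm.elbow + 0.1 * arm.axis)
        a_fwd = sweep_angle_deg(pose_fwd, arm)
        a_back = sweep_angle_deg(pose_back, arm)
        assert abs(abs(a_fwd) - 20) < 1e-6
        assert abs(abs(a_back) - 20) < 1e-6
        assert a_fwd * a_back < 0

    def test_scripted_elbow_wrist_path_covers_all_bins(self, arm):
        """200-pose straight path: u non-decreasing and covering 1..35."""
        grid = AtlasGrid()
        us = []
        for s in np.linspace(0, 1, 200):
            pose = make_pose(tilt_deg=0,
                             position=(1 - s) * arm.elbow + s * arm.wrist)
            us.append(probe_to_frame_key(pose, arm, grid).u)
        assert us[0] == 1 and us[-1] == 35
        assert all(b >= a for a, b in zip(us, us[1:]))
        assert set(us) == set(range(1, 36))

    def test_lateral_selection_spans_bins(self, arm):
        grid = AtlasGrid()
        vs = []
        for c in np.linspace(-0.039, 0.039, 50):
            pose = make_pose(
                tilt_deg=0,
                position=arm.elbow + 0.1 * arm.axis + c * arm.cross_axis)
            vs.append(probe_to_frame_key(pose, arm, grid).v)
        assert min(vs) == 1 and max(vs) == 10
        assert all(b >= a for a, b in zip(vs, vs[1:]))

    def test_unknown_mode_rejected(self, arm):
        grid = AtlasGrid(modes=(BMODE,))
        pose = make_pose(position=arm.elbow)
        with pytest.raises(KeyError):
            probe_to_frame_key(pose, arm, grid, mode=DOPPLER)


class TestArmLength:
    def test_distance_from_registration(self):
        pts = {j: np.zeros(3) for j in JOINT_ORDER}
        pts["left_elbow"] = np.array([0.0, 0.0, 0.0])
        pts["left_hand"] = np.array([0.3, 0.0, 0.0])
        pts["left_shoulder"] = np.array([0.0, 0.3, 0.0])
        pts["right_hand"] = np.array([0.0, 0.0, 0.3])
        reg = RegistrationSet(points_a=pts, points_bt=pts)
        assert arm_length_from_registration(reg) == pytest.approx(0.3)

    def test_coincident_joints_rejected(self):
        pts = {j: np.array([float(i), 0, 0])
               for i, j in enumerate(JOINT_ORDER)}
        pts["left_hand"] = pts["left_elbow"].copy()
        reg = RegistrationSet(points_a=pts, points_bt=pts)
        with pytest.raises(ValueError):
            arm_length_from_registration(reg)

    def test_seeded_fixtures_match_direct_computation(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            pts = {j: rng.normal(size=3) for j in JOINT_ORDER}
            reg = RegistrationSet(points_a=pts, points_bt=pts)
            want = np.linalg.norm(pts["left_hand"] - pts["left_elbow"])
            assert arm_length_from_registration(reg) == pytest.approx(want)


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        grid = AtlasGrid(n_long=5, n_lat=3, n_sweep=4, beta_deg=25.0)
        path = save_manifest(grid, tmp_path / "manifest.json")
        restored = load_manifest(path)
        assert restored == grid

    def test_small_synthetic_atlas_complete(self, tmp_path):
        grid = AtlasGrid(n_long=3, n_lat=2, n_sweep=4)
        generate_atlas(grid, seed=0, out_dir=tmp_path, clip_fps=5.0,
                       clip_duration_s=1.0)
        restored = load_manifest(tmp_path / "manifest.json")
        for mode in restored.modes:
            for key in restored.keys(mode):
                img = get_frame(tmp_path, restored, key)
                assert img.shape[0] > 0

    def test_get_frame_out_of_range_key(self, tmp_path):
        grid = AtlasGrid(n_long=2, n_lat=1, n_sweep=2, modes=(BMODE,))
        generate_atlas(grid, seed=0, out_dir=tmp_path)
        with pytest.raises(KeyError):
            get_frame(tmp_path, grid, FrameKey(BMODE, 3, 1, 1))

    def test_get_frame_missing_file_lists_key(self, tmp_path):
        grid = AtlasGrid(n_long=2, n_lat=1, n_sweep=2, modes=(BMODE,))
        generate_atlas(grid, seed=0, out_dir=tmp_path)
        key = FrameKey(BMODE, 1, 1, 1)
        frame_path(tmp_path, key).unlink()
        with pytest.raises(FileNotFoundError, match="u=1"):
            get_frame(tmp_path, grid, key)


def test_clip_frame_index_loops():
    from arustrain.atlas import DopplerClip
    clip = DopplerClip(key=FrameKey(DOPPLER, 1, 1, 1), path="c", fps=10.0,
                       duration_s=10.0)
    assert clip.n_frames == 100
    assert clip_frame_index(clip, 0.0) == 0
    assert clip_frame_index(clip, 0.55) == 5
    assert clip_frame_index(clip, 10.0) == 0  # loops
    with pytest.raises(ValueError):
        clip_frame_index(clip, -1.0)
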