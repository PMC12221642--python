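import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from pigeongaze.config import default_scene_config
from pigeongaze.datatypes import CalibrationError, HeadPoseSeries
from pigeongaze.headpose import (
    angular_speed,
    build_head_frame,
    detect_grooming,
    detect_saccades,
    median_orientation,
    reconstruct_poses,
    rigid_align,
    smooth_poses,
)
from pigeongaze.synthetic import default_calibration


def _template():
    return default_calibration().template


class TestRigidAlign:
    def test_exact_rotation_recovered(self):
        tpl = _template()
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        obs = tpl @ rot.T + np.array([0.5, -0.2, 1.0])
        r, t, rmsd = rigid_align(obs, tpl)
        assert np.allclose(r, rot, atol=1e-12)
        assert rmsd < 1e-12

    def test_rmsd_tracks_noise_scale(self):
        tpl = _template()
        rng = np.random.default_rng(42)
        rmsds = []
        for _ in range(200):
            obs = tpl + rng.normal(0, 1e-3, tpl.shape)
            rmsds.append(rigid_align(obs, tpl)[2])
        # rmsd pools 3 coords per marker and Kabsch absorbs 6 of 3N=12 dof:
        # E[rmsd^2] = (3N - 6)/N * sd^2 = 1.5 sd^2, i.e. rmsd ~ 1.22 sd
        assert 1.0e-3 < np.mean(rmsds) < 1.45e-3

    def test_never_returns_reflection(self):
        tpl = _template()
        rng = np.random.default_rng(7)
        for _ in range(50):
            obs = tpl + rng.normal(0, 0.02, tpl.shape)  # noise >> marker spread
            r, _, _ = rigid_align(obs, tpl)
            assert np.linalg.det(r) > 0.99

    def test_too_few_markers_yields_none(self):
        tpl = _template()
        obs = tpl.copy()
        valid = np.array([True, True, False, False])
        assert rigid_align(obs, tpl, valid) is None


class TestBuildHeadFrame:
    def test_symmetric_geometry_gives_forward_y(self):
        o, r = build_head_frame(
            np.array([-0.01, 0, 0]), np.array([0.01, 0, 0]), np.array([0, 0.0173, -0.01])
        )
        assert np.allclose(o, 0)
        assert np.allclose(r[:, 1], [0, 1, 0], atol=1e-3)

    def test_beak_elevation_is_minus_30(self):
        o, r = build_head_frame(
            np.array([-0.01, 0, 0]), np.array([0.01, 0, 0]), np.array([0, 0.0173, -0.01])
        )
        beak = np.array([0, 0.0173, -0.01])
        bh = r.T @ (beak - o)
        bh /= np.linalg.norm(bh)
        assert abs(np.degrees(np.arcsin(bh[2])) + 30.0) < 1e-6
        assert abs(np.degrees(np.arctan2(bh[0], bh[1]))) < 1e-6

    @given(
        st.integers(0, 10_000),
        st.floats(-60, 60),
        st.floats(-30, 30),
    )
    def test_frame_is_proper_rotation(self, seed, yaw, pitch):
        """Any non-degenerate eye/beak geometry yields an orthonormal,
        right-handed frame."""
        rng = np.random.default_rng(seed)
        rot = Rotation.from_euler("zyx", [yaw, pitch, rng.uniform(-20, 20)], degrees=True)
        le = rot.apply([-0.011, 0.001, 0.0])
        re = rot.apply([0.009, 0.0, 0.001])
        bk = rot.apply([0.001, 0.018, -0.009])
        o, r = build_head_frame(le, re, bk)
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_world_transform_recovers_rotation(self, calib):
        """Transforming calibration points by a known pose and rebuilding the
        frame recovers that pose (compose/invert check)."""
        o0, r0 = build_head_frame(
            calib.left_eye, calib.right_eye, calib.beak_tip, head_up_hint=calib.head_up
        )
        true = Rotation.from_euler("zxy", [35, -12, 7], degrees=True).as_matrix()
        shift = np.array([0.3, -1.1, 0.9])
        o1, r1 = build_head_frame(
            true @ calib.left_eye + shift,
            true @ calib.right_eye + shift,
            true @ calib.beak_tip + shift,
            head_up_hint=true @ calib.head_up,
        )
        assert np.allclose(r1, true @ r0, atol=1e-10)
        assert np.allclose(o1, true @ o0 + shift, atol=1e-12)

    def test_degenerate_beak_raises(self):
        with pytest.raises(CalibrationError):
            build_head_frame(
                np.array([-0.01, 0, 0]), np.array([0.01, 0, 0]), np.array([0.02, 0, 0])
            )


def _constant_pose_series(n=60, frame_rate=60.0):
    rot = np.tile(np.eye(3), (n, 1, 1))
    origin = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
    return HeadPoseSeries(frame_rate, origin, rot, np.ones(n, dtype=bool))


class TestSmoothing:
    def test_short_gap_filled_with_constant_pose(self, config):
        poses = _constant_pose_series()
        poses.valid[20:23] = False
        out = smooth_poses(poses, config)
        assert out.valid.all()
        assert np.allclose(out.origin, poses.origin[0], atol=1e-9)
        assert np.allclose(out.rot[21], np.eye(3), atol=1e-9)

    def test_long_gap_stays_invalid(self, config):
        poses = _constant_pose_series(n=200)
        poses.valid[50:120] = False  # 70 frames >> max_gap
        out = smooth_poses(poses, config)
        assert not out.valid[60]
        assert out.valid[:50].all() and out.valid[120:].all()

    def test_noise_jitter_is_reduced(self, config):
        rng = np.random.default_rng(3)
        n = 400
        rot = Rotation.from_rotvec(rng.normal(0, np.deg2rad(1.0), (n, 3))).as_matrix()
        poses = HeadPoseSeries(60.0, np.zeros((n, 3)), rot, np.ones(n, dtype=bool))
        out = smooth_poses(poses, config)
        raw_speed = np.nanmean(angular_speed(poses))
        smooth_speed = np.nanmean(angular_speed(out))
        assert smooth_speed < raw_speed


class TestSaccades:
    def test_static_head_unflagged(self):
        assert not detect_saccades(_constant_pose_series(), 300.0).any()

    def test_single_jump_flags_exactly_the_jump_frame(self):
        n = 40
        rot = np.tile(np.eye(3), (n, 1, 1))
        jump = Rotation.from_euler("z", 20, degrees=True).as_matrix()
        rot[25:] = jump
        poses = HeadPoseSeries(100.0, np.zeros((n, 3)), rot, np.ones(n, dtype=bool))
        mask = detect_saccades(poses, 300.0)  # 20 deg in 10 ms = 2000 deg/s
        assert mask[25]
        assert mask.sum() == 1

    def test_scheduled_saccades_recovered_on_generated_data(self, flock):
        """Every scheduled wander transition appears in the mask within one
        frame (median pre-filter can shift the flag by one)."""
        bird = "p00"
        mask = flock["result"].masks[bird].saccade
        flagged = set(np.flatnonzero(mask).tolist())
        truth = flock["truth"].saccade_frames[bird]
        hits = sum(bool({t - 1, t, t + 1} & flagged) for t in truth)
        assert hits / len(truth) > 0.95


class TestGrooming:
    def test_pitched_down_head_near_back_is_flagged(self, config):
        n = 120
        down = Rotation.from_euler("x", -60, degrees=True).as_matrix()
        rot = np.tile(down, (n, 1, 1))
        origin = np.tile(np.array([0.0, 0.05, 0.07]), (n, 1))
        poses = HeadPoseSeries(60.0, origin, rot, np.ones(n, dtype=bool))
        backpack = np.tile(np.array([0.0, 0.0, 0.02]), (n, 1))
        mask = detect_grooming(poses, backpack, config)
        assert mask.all()

    def test_upright_scanning_head_unflagged(self, config):
        n = 120
        poses = _constant_pose_series(n)
        backpack = np.tile(np.array([0.0, 0.0, 0.75]), (n, 1))
        assert not detect_grooming(poses, backpack, config).any()

    def test_external_mask_passes_through(self, config):
        poses = _constant_pose_series(50)
        ext = np.zeros(50, dtype=bool)
        ext[10:20] = True
        out = detect_grooming(poses, np.zeros((50, 3)), config, external_mask=ext)
        assert np.array_equal(out, ext)


class TestReconstruction:
    def test_noiseless_recovery_within_half_degree(self, calib):
        """Emitting markers from a known pose and reconstructing recovers the
        orientation essentially exactly when there is no noise."""
        true = Rotation.from_euler("zyx", [40, 10, -5], degrees=True).as_matrix()
        origin = np.array([0.2, 0.4, 0.9])
        n = 10
        head = origin + (calib.template @ true.T)[None, :, :]
        head = np.tile(head, (n, 1, 1))
        from pigeongaze.datatypes import BirdTracks

        tracks = BirdTracks(
            head=head,
            head_valid=np.ones((n, 4), dtype=bool),
            backpack=np.zeros((n, 0, 3)),
            backpack_valid=np.zeros((n, 0), dtype=bool),
        )
        poses = reconstruct_poses(tracks, calib, 60.0)
        assert poses.valid.all()
        # generating pose's head frame: calibration frame carried by `true`
        o0, r0 = build_head_frame(
            calib.left_eye, calib.right_eye, calib.beak_tip, head_up_hint=calib.head_up
        )
        expected = true @ r0
        err = Rotation.from_matrix(poses.rot[0].T @ expected).magnitude()
        assert np.degrees(err) < 0.5
        assert np.allclose(poses.origin[0], true @ o0 + origin, atol=1e-9)

    def test_equivariance_under_global_rigid_transform(self, calib):
        """Rigidly moving all markers moves origins and rotations identically."""
        rng = np.random.default_rng(11)
        n = 5
        from pigeongaze.datatypes import BirdTracks

        base = Rotation.random(n, random_state=1).as_matrix()
        origin = rng.normal(0, 0.5, (n, 3))
        head = origin[:, None, :] + np.einsum("nij,mj->nmi", base, calib.template)
        tracks = BirdTracks(
            head, np.ones((n, 4), dtype=bool), np.zeros((n, 0, 3)), np.zeros((n, 0), dtype=bool)
        )
        poses = reconstruct_poses(tracks, calib, 60.0)
        g = Rotation.from_euler("zxz", [17, 33, -40], degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        head2 = np.einsum("ij,nmj->nmi", g, head) + shift
        tracks2 = BirdTracks(
            head2, np.ones((n, 4), dtype=bool), np.zeros((n, 0, 3)), np.zeros((n, 0), dtype=bool)
        )
        poses2 = reconstruct_poses(tracks2, calib, 60.0)
        assert np.allclose(poses2.origin, poses.origin @ g.T + shift, atol=1e-9)
        assert np.allclose(poses2.rot, np.einsum("ij,njk->nik", g, poses.rot), atol=1e-9)

    def test_masks_are_subsets_of_valid_frames(self, flock):
        for bird, mask in flock["result"].masks.items():
            valid = flock["result"].poses[bird].valid
            assert not (mask.saccade & ~valid).any()
            assert not (mask.grooming & ~valid).any()


def test_median_orientation_preserves_steps():
    """The median differentiator pre-filter does not smear an orientation
    step across neighboring frames."""
    n = 30
    rot = np.tile(np.eye(3), (n, 1, 1))
    rot[15:] = Rotation.from_euler("z", 40, degrees=True).as_matrix()
    poses = HeadPoseSeries(60.0, np.zeros((n, 3)), rot, np.ones(n, dtype=bool))
    out = median_orientation(poses, window=5)
    assert np.allclose(out.rot[13], np.eye(3), atol=1e-9)
    assert np.allclose(out.rot[16], rot[16], atol=1e-9)
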