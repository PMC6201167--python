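"""Planar frames, transforms, the two-instant joint solve and angle conventions."""

import numpy as np
import pytest

from stafree import (
    CycleGrid,
    PlanarPose,
    PoseSeries,
    compose,
    joint_angles,
    joint_residual,
    pair_frame,
    pair_frame_series,
    relative_frame,
    solve_joint_all_instants,
    solve_joint_two_instants,
    to_global,
    to_local,
)
from stafree.errors import DegenerateMotionError, DegeneratePairError


class TestPairFrame:
    def test_horizontal_pair_is_identity_rotation(self):
        pose = pair_frame((1.0, 1.0), (3.0, 1.0))
        np.testing.assert_allclose(pose.origin, [2.0, 1.0])
        np.testing.assert_allclose(pose.rotation, np.eye(2), atol=1e-15)

    def test_vertical_pair_rotates_90deg_ccw(self):
        pose = pair_frame((0.0, 0.0), (0.0, 2.0))
        np.testing.assert_allclose(pose.origin, [0.0, 1.0])
        np.testing.assert_allclose(pose.rotation, [[0.0, -1.0], [1.0, 0.0]], atol=1e-15)

    def test_coincident_pair_rejected(self):
        with pytest.raises(DegeneratePairError):
            pair_frame((1.0, 2.0), (1.0, 2.0))

    def test_always_proper_rotation(self):
        rng = np.random.default_rng(5)
        p1 = rng.normal(size=(50, 2))
        p2 = p1 + rng.normal(size=(50, 2))
        series = pair_frame_series(p1, p2)
        rt_r = np.swapaxes(series.rotations, 1, 2) @ series.rotations
        np.testing.assert_allclose(rt_r, np.broadcast_to(np.eye(2), (50, 2, 2)), atol=1e-12)
        np.testing.assert_allclose(np.linalg.det(series.rotations), 1.0, atol=1e-12)


class TestTransforms:
    def test_identity_pose_passthrough(self):
        np.testing.assert_allclose(
            to_global(PlanarPose.identity(), np.array([0.2, 0.0])), [0.2, 0.0]
        )

    def test_rotation_90_with_offset(self):
        pose = PlanarPose.from_angle([1.0, 0.0], np.pi / 2)
        np.testing.assert_allclose(to_global(pose, np.array([1.0, 0.0])), [1.0, 1.0], atol=1e-15)

    def test_round_trip_random_points(self):
        rng = np.random.default_rng(1)
        pose = PlanarPose.from_angle(rng.normal(size=2), rng.uniform(-np.pi, np.pi))
        pts = rng.normal(size=(100, 2))
        np.testing.assert_allclose(to_local(pose, to_global(pose, pts)), pts, atol=1e-12)

    def test_compose_identity(self):
        x = PlanarPose.from_angle([0.3, -0.2], 0.7)
        composed = compose(PlanarPose.identity(), x)
        np.testing.assert_allclose(composed.origin, x.origin)
        np.testing.assert_allclose(composed.rotation, x.rotation)

    def test_relative_of_equal_poses_is_identity(self):
        x = PlanarPose.from_angle([0.3, -0.2], 0.7)
        rel = relative_frame(x, x)
        np.testing.assert_allclose(rel.origin, 0.0, atol=1e-15)
        np.testing.assert_allclose(rel.rotation, np.eye(2), atol=1e-15)

    def test_compose_relative_round_trip(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            parent = PlanarPose.from_angle(rng.normal(size=2), rng.uniform(-np.pi, np.pi))
            child = PlanarPose.from_angle(rng.normal(size=2), rng.uniform(-np.pi, np.pi))
            back = compose(parent, relative_frame(child, parent))
            np.testing.assert_allclose(back.origin, child.origin, atol=1e-12)
            np.testing.assert_allclose(back.rotation, child.rotation, atol=1e-12)


class TestJointSolve:
    def _hinge(self, n=40):
        grid = CycleGrid(n)
        phi = grid.phases
        fa = PoseSeries.from_angles(
            np.column_stack([np.cos(phi) * 0.1, np.sin(phi) * 0.1]), 0.4 * np.sin(phi)
        )
        j_a = np.array([0.25, 0.05])
        j_b = np.array([-0.2, 0.03])
        jg = to_global(fa, j_a)
        rot_b = PoseSeries.from_angles(np.zeros((n, 2)), 0.9 * np.cos(phi)).rotations
        fb = PoseSeries(jg - np.einsum("nij,j->ni", rot_b, j_b), rot_b)
        return fa, fb, j_a, j_b

    def test_recovers_known_locals(self):
        fa, fb, j_a, j_b = self._hinge()
        sa, sb = solve_joint_two_instants(fa, fb, 0, 10)
        np.testing.assert_allclose(sa, j_a, atol=1e-10)
        np.testing.assert_allclose(sb, j_b, atol=1e-10)
        res, total = joint_residual(fa, fb, sa, sb)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)
        assert total < 1e-8

    def test_identical_relative_rotation_is_singular(self):
        grid = CycleGrid(8)
        fa = PoseSeries.from_angles(np.zeros((8, 2)), np.full(8, 0.3))
        fb = PoseSeries.from_angles(np.ones((8, 2)), np.full(8, -0.2))
        with pytest.raises(DegenerateMotionError):
            solve_joint_two_instants(fa, fb, 0, 4)

    def test_identity_frames_give_global_minus_origin(self):
        n = 4
        fa = PoseSeries.from_angles(np.tile([1.0, 0.0], (n, 1)), np.zeros(n))
        fb = PoseSeries.from_angles(np.tile([0.0, 1.0], (n, 1)), np.linspace(0, 1, n))
        g = np.array([2.0, 2.0])
        # fabricate: joint at fixed global g for both
        fb = PoseSeries(
            np.tile(g, (n, 1)) - np.einsum("nij,j->ni", fb.rotations, np.array([0.3, 0.1])),
            fb.rotations,
        )
        sa, sb = solve_joint_two_instants(fa, fb, 0, 2)
        np.testing.assert_allclose(sa, g - [1.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(sb, [0.3, 0.1], atol=1e-10)

    def test_all_instants_agrees_on_rigid_data(self):
        fa, fb, j_a, j_b = self._hinge()
        sa, sb, report = solve_joint_all_instants(fa, fb)
        np.testing.assert_allclose(sa, j_a, atol=1e-10)
        np.testing.assert_allclose(sb, j_b, atol=1e-10)
        assert report["rank"] == 4

    def test_residual_shift_with_identity_rotations(self):
        n = 6
        fa = PoseSeries.from_angles(np.zeros((n, 2)), np.zeros(n))
        fb = PoseSeries.from_angles(np.zeros((n, 2)), np.zeros(n))
        delta = np.array([0.01, -0.02])
        res, total = joint_residual(fa, fb, delta, np.zeros(2))
        np.testing.assert_allclose(res, np.tile(delta, (n, 1)), atol=1e-15)
        assert total == pytest.approx(n * np.linalg.norm(delta), rel=1e-12)

    def test_residual_matches_brute_force(self):
        fa, fb, j_a, j_b = self._hinge()
        ja = j_a + [0.01, 0.0]
        res, _ = joint_residual(fa, fb, ja, j_b)
        for n in range(0, len(fa), 7):
            brute = (fa.origins[n] + fa.rotations[n] @ ja) - (
                fb.origins[n] + fb.rotations[n] @ j_b
            )
            np.testing.assert_allclose(res[n], brute, atol=1e-14)


class TestAngles:
    def test_fixture_angle_round_trip(self, gait_fixture):
        """Recomputing angles from the generated link poses reproduces the inputs."""
        kin = gait_fixture.kinematics
        out = joint_angles(kin.link_poses, gait_fixture.topology)
        for key, series in kin.angles.items():
            np.testing.assert_allclose(out[key], series, atol=1e-12, err_msg=key)

    def test_clockwise_positive_sign(self, gait_fixture):
        """Rotating the distal link clockwise increases the joint angle."""
        topo = gait_fixture.topology
        poses = dict(gait_fixture.kinematics.link_poses)
        base = joint_angles(poses, topo)["l-K"]
        shank = poses["l-S"]
        # clockwise rotation = negative CCW frame angle increment
        poses["l-S"] = PoseSeries.from_angles(shank.origins, shank.angles - 0.3)
        turned = joint_angles(poses, topo)["l-K"]
        np.testing.assert_allclose(turned - base, 0.3, atol=1e-12)

    def test_equivariance_under_global_rigid_motion(self):
        fa, fb, j_a, j_b = TestJointSolve()._hinge()
        motion = PlanarPose.from_angle([3.0, -1.0], 0.8)
        fa2, fb2 = fa.transformed(motion), fb.transformed(motion)
        _, total = joint_residual(fa, fb, j_a, j_b)
        _, total2 = joint_residual(fa2, fb2, j_a, j_b)
        assert abs(total - total2) < 1e-10
        sa, sb = solve_joint_two_instants(fa2, fb2, 0, 10)
        np.testing.assert_allclose(sa, j_a, atol=1e-10)
        np.testing.assert_allclose(sb, j_b, atol=1e-10)
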