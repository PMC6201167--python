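"""The full periodic-STA assimilation: linear stage, reconstruction, pipeline."""

import numpy as np
import pytest

from stafree import (
    CycleGrid,
    FourierCoeffs2D,
    PlanarPose,
    ShapeParams,
    assimilate_periodic,
    marker_frame_in_landmark,
    naive_assimilate,
    solve_joint_two_instants,
)
from stafree.errors import SolverError
from stafree.fourier import eval_series
from stafree.frames import joint_residual, marker_frames
from stafree.periodic import _LinearSystem

from conftest import make_two_link


class TestMarkerFrameInLandmark:
    def test_zero_xi_gives_identity_tilt(self):
        grid = CycleGrid(40)
        q = FourierCoeffs2D(2, [0.01, 0.0, 0.0, 0.005], [0.0, 0.002, 0.0, 0.0])
        shape = ShapeParams(0.4, np.zeros(4), np.zeros(4))
        offsets, tilt, rot = marker_frame_in_landmark(shape, q, grid)
        np.testing.assert_allclose(tilt, 0.0, atol=1e-15)
        np.testing.assert_allclose(rot, np.broadcast_to(np.eye(2), (40, 2, 2)), atol=1e-15)
        # q1 = q2 = q: offset is the STA series itself
        np.testing.assert_allclose(offsets, eval_series(q, grid), atol=1e-14)

    def test_small_transverse_sine_tilt(self):
        grid = CycleGrid(100)
        c, eps = 0.4, 1e-4
        shape = ShapeParams(c, np.zeros(2), [0.0, eps])  # single sine in xi_y
        _, tilt, _ = marker_frame_in_landmark(shape, FourierCoeffs2D.zeros(1), grid)
        expected = (eps / c) * np.sin(grid.phases)
        np.testing.assert_allclose(tilt, expected, atol=(eps / c) ** 2)

    def test_rotations_always_proper(self):
        grid = CycleGrid(50)
        rng = np.random.default_rng(2)
        shape = ShapeParams(0.3, rng.normal(0, 0.01, 4), rng.normal(0, 0.01, 4))
        _, _, rot = marker_frame_in_landmark(shape, FourierCoeffs2D.zeros(2), grid)
        np.testing.assert_allclose(np.linalg.det(rot), 1.0, atol=1e-12)

    def test_markers_crossing_rejected(self):
        grid = CycleGrid(50)
        shape = ShapeParams(0.05, [-0.06, 0.0, 0.0, 0.0], np.zeros(4))
        with pytest.raises(SolverError):
            marker_frame_in_landmark(shape, FourierCoeffs2D.zeros(2), grid)


class TestLinearStage:
    def test_unknown_count_seven_link(self, gait_fixture):
        system = _LinearSystem(
            gait_fixture.markers, gait_fixture.topology, gait_fixture.markers.grid, 4
        )
        # 7 links x 4K coefficients + 12 link-joint incidences x 2
        assert system.n_unknowns == 7 * 16 + 12 * 2 == 136


class TestPipeline:
    def test_two_link_exact_recovery(self, two_link):
        toy = two_link
        res = assimilate_periodic(toy.markers, toy.topology, order=2)
        for (link, j), prof in toy.profiles.profiles.items():
            np.testing.assert_allclose(res.sta[(link, j)].qx, prof.qx, atol=1e-8)
            np.testing.assert_allclose(res.sta[(link, j)].qy, prof.qy, atol=1e-8)
        for key, truth in toy.joint_locals.items():
            np.testing.assert_allclose(res.joint_locals[key], truth, atol=1e-8)
        np.testing.assert_allclose(res.joint_trajectories["J"], toy.joint_global, atol=1e-8)
        for slot, clean in toy.landmarks.positions.items():
            np.testing.assert_allclose(
                res.landmark_markers.positions[slot], clean, atol=1e-8
            )

    def test_zero_sta_identity(self, two_link_clean):
        toy = two_link_clean
        res = assimilate_periodic(toy.markers, toy.topology, order=2)
        for slot, arr in toy.markers.positions.items():
            np.testing.assert_allclose(res.landmark_markers.positions[slot], arr, atol=1e-10)
        for coeffs in res.sta.values():
            np.testing.assert_allclose(coeffs.as_stacked(), 0.0, atol=1e-10)
        # locals agree with the closed-form two-instant solve on the raw frames
        frames = marker_frames(toy.markers, toy.topology)
        ja, jb = solve_joint_two_instants(frames["A"], frames["B"], 0, 16)
        np.testing.assert_allclose(res.joint_locals[("A", "J")], ja, atol=1e-9)
        np.testing.assert_allclose(res.joint_locals[("B", "J")], jb, atol=1e-9)

    def test_idempotence_on_corrected_output(self, two_link):
        toy = two_link
        first = assimilate_periodic(toy.markers, toy.topology, order=2)
        second = assimilate_periodic(first.landmark_markers, toy.topology, order=2)
        for coeffs in second.sta.values():
            np.testing.assert_allclose(coeffs.as_stacked(), 0.0, atol=1e-8)

    def test_recovered_distance_constant(self, two_link):
        toy = two_link
        res = assimilate_periodic(toy.markers, toy.topology, order=2)
        for link in ("A", "B"):
            dist = np.linalg.norm(
                res.landmark_markers.get(link, 2) - res.landmark_markers.get(link, 1),
                axis=1,
            )
            np.testing.assert_allclose(dist, res.shapes[link].C, atol=1e-9)

    def test_joint_residual_not_worse_than_naive(self, two_link):
        toy = two_link
        res = assimilate_periodic(toy.markers, toy.topology, order=2)
        naive = naive_assimilate(toy.markers, toy.topology)
        _, periodic_cost = joint_residual(
            res.landmark_frames["A"],
            res.landmark_frames["B"],
            res.joint_locals[("A", "J")],
            res.joint_locals[("B", "J")],
        )
        assert periodic_cost <= naive.report["cost_sum_norm"] + 1e-12

    def test_pipeline_equivariance(self, two_link):
        toy = two_link
        motion = PlanarPose.from_angle([0.7, -2.0], 1.1)
        res = assimilate_periodic(toy.markers, toy.topology, order=2)
        res2 = assimilate_periodic(toy.markers.transformed(motion), toy.topology, order=2)
        np.testing.assert_allclose(
            res2.joint_trajectories["J"],
            res.joint_trajectories["J"] @ motion.rotation.T + motion.origin,
            atol=1e-8,
        )
        for key in res.joint_locals:
            np.testing.assert_allclose(res2.joint_locals[key], res.joint_locals[key], atol=1e-7)

    def test_seeded_sta_parameter_recovery(self):
        """Noiseless parameter recovery below 1e-6 for moderate-amplitude STA."""
        toy = make_two_link(n_samples=80, order=3, amplitude=0.02, seed=6)
        res = assimilate_periodic(toy.markers, toy.topology, order=3)
        for slot, prof in toy.profiles.profiles.items():
            np.testing.assert_allclose(res.sta[slot].qx, prof.qx, atol=1e-6)
            np.testing.assert_allclose(res.sta[slot].qy, prof.qy, atol=1e-6)
        for key, truth in toy.joint_locals.items():
            np.testing.assert_allclose(res.joint_locals[key], truth, atol=1e-6)

    def test_deterministic(self, two_link):
        toy = two_link
        a = assimilate_periodic(toy.markers, toy.topology, order=2)
        b = assimilate_periodic(toy.markers, toy.topology, order=2)
        for key in a.joint_angles:
            assert np.array_equal(a.joint_angles[key], b.joint_angles[key])
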