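"""Spectral differentiation and planar Newton-Euler inverse dynamics."""

import numpy as np
import pytest

from stafree import (
    CycleGrid,
    naive_assimilate,
    newton_euler_link,
    spectral_derivative,
)
from stafree.dynamics import GRAVITY, evaluate_assimilation, inverse_dynamics_planar
from stafree.errors import InputError
from stafree.gait import GaitOptions, GroundReaction, generate_grf


class TestSpectralDerivative:
    def test_constant_has_zero_derivative(self):
        grid = CycleGrid(40, duration=1.3)
        out = spectral_derivative(np.full(40, 2.5), grid)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_first_derivative_of_sine(self):
        period = 0.8
        grid = CycleGrid(64, duration=period)
        t = grid.times
        out = spectral_derivative(np.sin(2 * np.pi * t / period), grid)
        np.testing.assert_allclose(out, (2 * np.pi / period) * np.cos(2 * np.pi * t / period), atol=1e-10)

    def test_second_derivative_of_third_harmonic(self):
        period = 1.1
        grid = CycleGrid(80, duration=period)
        t = grid.times
        w = 2 * np.pi * 3 / period
        out = spectral_derivative(np.cos(w * t), grid, order=2)
        np.testing.assert_allclose(out, -(w**2) * np.cos(w * t), atol=1e-9)

    def test_missing_duration_rejected(self):
        with pytest.raises(InputError):
            spectral_derivative(np.zeros(16), CycleGrid(16))


class TestNewtonEuler:
    def test_static_horizontal_link_gravity_torque(self):
        """Uniform link held horizontally at a pin: support torque m*g*d (CCW)."""
        grid = CycleGrid(32, duration=1.0)
        m, d = 2.0, 0.3
        com = np.tile([d, 0.0], (32, 1))  # pin at origin, CoM d to the right
        f, t = newton_euler_link(m, 0.05, com, np.zeros(32), np.zeros(2), grid)
        np.testing.assert_allclose(f, np.tile([0.0, m * GRAVITY], (32, 1)), atol=1e-8)
        np.testing.assert_allclose(t, m * GRAVITY * d, atol=1e-8)

    def _pendulum(self, n=128, period=1.0, theta0=0.4, m=1.5, d=0.25, i_com=0.02):
        grid = CycleGrid(n, duration=period)
        t = grid.times
        theta = theta0 * np.sin(2 * np.pi * t / period)  # CCW from straight down
        com = np.column_stack([d * np.sin(theta), -d * np.cos(theta)])
        return grid, t, theta, com, m, d, i_com

    def test_pendulum_matches_closed_form(self):
        grid, t, theta, com, m, d, i_com = self._pendulum()
        _, tau = newton_euler_link(m, i_com, com, theta, np.zeros(2), grid)
        period = grid.duration
        theta_dd = -((2 * np.pi / period) ** 2) * theta
        expected = (i_com + m * d**2) * theta_dd + m * GRAVITY * d * np.sin(theta)
        np.testing.assert_allclose(tau, expected, atol=1e-6 * np.abs(expected).max())

    def test_pendulum_energy_consistency(self):
        """A conservative prescribed cycle does zero net work: closed-loop
        integral of tau * theta_dot vanishes."""
        grid, t, theta, com, m, d, i_com = self._pendulum()
        _, tau = newton_euler_link(m, i_com, com, theta, np.zeros(2), grid)
        theta_dot = spectral_derivative(theta, grid)
        work = np.mean(tau * theta_dot) * grid.duration
        assert abs(work) < 1e-6


class TestSevenLink:
    def test_truth_torques_deterministic(self, gait_fixture):
        fix = gait_fixture
        grid = fix.markers.grid
        args = (fix.kinematics.link_poses, fix.kinematics.joint_trajectories, fix.params, fix.grf, grid)
        a = inverse_dynamics_planar(*args)
        b = inverse_dynamics_planar(*args)
        for key in a:
            assert np.array_equal(a[key], b[key])

    def test_torques_linear_in_grf(self, gait_fixture):
        """Torques are affine in the applied GRF for fixed kinematics, so
        supplying the *same* GRF to truth and estimate removes every
        GRF-dependent term from their torque difference."""
        fix = gait_fixture
        grid = fix.markers.grid
        grf2 = generate_grf(
            grid, fix.params,
            GaitOptions(stance_fraction=0.5, grf_second_hump=0.3),
            kinematics=fix.kinematics, topology=fix.topology,
        )
        zero = GroundReaction(
            {s: np.zeros_like(f) for s, f in fix.grf.forces.items()},
            fix.grf.cops,
            fix.grf.stance,
        )
        both = GroundReaction(
            {s: fix.grf.forces[s] + grf2.forces[s] for s in fix.grf.forces},
            fix.grf.cops,
            fix.grf.stance,
        )
        grf2_same_cop = GroundReaction(grf2.forces, fix.grf.cops, fix.grf.stance)
        kin = (fix.kinematics.link_poses, fix.kinematics.joint_trajectories)
        t1 = inverse_dynamics_planar(*kin, fix.params, fix.grf, grid)
        t2 = inverse_dynamics_planar(*kin, fix.params, grf2_same_cop, grid)
        t0 = inverse_dynamics_planar(*kin, fix.params, zero, grid)
        t12 = inverse_dynamics_planar(*kin, fix.params, both, grid)
        for key in t1:
            scale = max(1.0, np.abs(t12[key]).max())
            np.testing.assert_allclose(
                t1[key] + t2[key] - t0[key], t12[key], atol=1e-9 * scale
            )

    def test_matched_kinematics_difference_grf_independent(self, gait_fixture):
        """For kinematics that agree (truth vs the periodic estimate), the
        torque difference stays at the noise floor under any shared GRF."""
        from stafree import assimilate_periodic

        fix = gait_fixture
        grid = fix.markers.grid
        res = assimilate_periodic(fix.markers, fix.topology)
        grf2 = generate_grf(
            grid, fix.params,
            GaitOptions(stance_fraction=0.55, grf_second_hump=0.5),
            kinematics=fix.kinematics, topology=fix.topology,
        )
        for grf in (fix.grf, grf2):
            t_true = inverse_dynamics_planar(
                fix.kinematics.link_poses, fix.kinematics.joint_trajectories,
                fix.params, grf, grid,
            )
            t_est = inverse_dynamics_planar(
                res.link_frames, res.joint_trajectories, fix.params, grf, grid
            )
            for key in t_true:
                assert np.abs(t_est[key] - t_true[key]).max() < 1e-6


class TestEvaluate:
    def test_identical_inputs_give_zero_errors(self, gait_fixture):
        fix = gait_fixture
        grid = fix.markers.grid
        torques = inverse_dynamics_planar(
            fix.kinematics.link_poses, fix.kinematics.joint_trajectories,
            fix.params, fix.grf, grid,
        )
        report = evaluate_assimilation(
            fix.kinematics.angles, torques, fix.kinematics.angles, torques
        )
        assert report.max_angle_error() == 0.0
        assert report.max_torque_error() == 0.0

    def test_naive_ankle_torque_error_in_stance(self, gait_fixture):
        fix = gait_fixture
        grid = fix.markers.grid
        t_true = inverse_dynamics_planar(
            fix.kinematics.link_poses, fix.kinematics.joint_trajectories,
            fix.params, fix.grf, grid,
        )
        naive = naive_assimilate(fix.markers, fix.topology)
        t_naive = inverse_dynamics_planar(
            naive.link_frames, naive.joint_trajectories, fix.params, fix.grf, grid
        )
        stance = fix.grf.stance["l"]
        stance_err = np.abs((t_naive["l-A"] - t_true["l-A"])[stance]).max()
        assert stance_err > 0.1  # N*m; the baseline visibly misestimates
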