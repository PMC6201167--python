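"""Planar inverse dynamics of the seven-link chain, with spectral derivatives.

Joint torques are computed by a bottom-up Newton-Euler recursion along each
leg (foot -> shank -> thigh) using the per-foot ground reaction force applied
at its center of pressure; the left and right hip torques come from their own
leg recursions (no residual redistribution through the HAT link).
Accelerations come from spectral differentiation of the periodic kinematics —
fit a truncated Fourier series, differentiate term by term, re-evaluate —
which is exact for band-limited signals.

Sign convention: joint angles are clockwise-positive (sagittal convention of
the seven-link model), so reported torques are clockwise-positive too, i.e.
the negative of the mathematical (counterclockwise) moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .fourier import CycleGrid, basis_matrix, fit_coeffs
from .frames import PoseSeries
from .gait import GRAVITY, GaitModelParams, GroundReaction

__all__ = [
    "spectral_derivative",
    "newton_euler_link",
    "inverse_dynamics_planar",
    "evaluate_assimilation",
]


def spectral_derivative(
    series: np.ndarray, grid: CycleGrid, order: int = 1, fit_order: int | None = None
) -> np.ndarray:
    """Time derivative of a periodic signal via Fourier fit and term-wise differentiation.

    ``series`` is ``(N,)`` or ``(N, d)``; ``order`` is 1 or 2.  The fit order
    defaults to ``(N - 2) // 4``, ample for smooth gait signals while leaving
    the fit overdetermined.
    """
    if grid.duration is None:
        raise InputError("spectral differentiation needs the cycle duration T")
    if order not in (1, 2):
        raise InputError(f"derivative order must be 1 or 2, got {order}")
    series = np.asarray(series, dtype=float)
    k_fit = fit_order if fit_order is not None else max(1, (grid.n_samples - 2) // 4)
    dc, coef = fit_coeffs(series, grid, k_fit, with_dc=True)
    k = np.arange(1, k_fit + 1)
    omega = 2.0 * np.pi * k / grid.duration
    a, b = coef[:k_fit], coef[k_fit:]
    if order == 1:
        # d/dt [a cos + b sin] = -a w sin + b w cos
        d_a, d_b = (omega.T * b.T).T, -(omega.T * a.T).T
        dc_out = np.zeros_like(np.asarray(dc, dtype=float))
    else:
        d_a, d_b = -((omega**2).T * a.T).T, -((omega**2).T * b.T).T
        dc_out = np.zeros_like(np.asarray(dc, dtype=float))
    design = basis_matrix(grid, k_fit)
    return dc_out + design @ np.concatenate([d_a, d_b])


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def newton_euler_link(
    mass: float,
    inertia: float,
    com: np.ndarray,
    angle: np.ndarray,
    prox: np.ndarray,
    grid: CycleGrid,
    dist: np.ndarray | None = None,
    f_dist: np.ndarray | None = None,
    t_dist: np.ndarray | None = None,
    f_ext: np.ndarray | None = None,
    r_ext: np.ndarray | None = None,
    fit_order: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Euler balance of one link: unknown proximal joint load.

    Given the link's CoM trajectory and (continuous) orientation angle, the
    known load at the distal joint (force ``f_dist`` and CCW torque ``t_dist``
    acting *on this link* at point ``dist``) and an optional external force
    ``f_ext`` at ``r_ext``, returns ``(f_prox, t_prox_ccw)`` — the force and
    CCW torque exerted on this link at the proximal joint ``prox``.  Gravity
    acts in -y.
    """
    com = np.asarray(com, float)
    acc = spectral_derivative(com, grid, order=2, fit_order=fit_order)
    alpha = spectral_derivative(np.asarray(angle, float), grid, order=2, fit_order=fit_order)
    n = com.shape[0]
    zero = np.zeros((n, 2))
    f_dist = zero if f_dist is None else np.asarray(f_dist, float)
    f_ext = zero if f_ext is None else np.asarray(f_ext, float)
    t_dist = np.zeros(n) if t_dist is None else np.asarray(t_dist, float)
    gravity = np.array([0.0, -mass * GRAVITY])
    f_prox = mass * acc - gravity - f_dist - f_ext
    moment = inertia * alpha
    moment -= _cross2(np.asarray(prox, float) - com, f_prox)
    moment -= t_dist
    if dist is not None:
        moment -= _cross2(np.asarray(dist, float) - com, f_dist)
    if r_ext is not None:
        moment -= _cross2(np.asarray(r_ext, float) - com, f_ext)
    return f_prox, moment


def inverse_dynamics_planar(
    link_poses: dict[str, PoseSeries],
    joint_trajectories: dict[str, np.ndarray],
    params: GaitModelParams,
    grf: GroundReaction,
    grid: CycleGrid,
    fit_order: int | None = None,
) -> dict[str, np.ndarray]:
    """Joint torques (N*m, clockwise positive) of the seven-link model.

    ``link_poses`` must be CoM-anchored link frames; ``joint_trajectories``
    the global joint positions.  The same GRF should be supplied when
    comparing torques across kinematics estimates, so that torque differences
    reflect kinematics only.
    """
    n = grid.n_samples
    for name, series in link_poses.items():
        if len(series) != n:
            raise InputError(f"pose series for {name!r} does not match the grid")
    for name, traj in joint_trajectories.items():
        if traj.shape != (n, 2):
            raise InputError(f"joint trajectory {name!r} does not match the grid")
    torques: dict[str, np.ndarray] = {}
    for side in ("l", "r"):
        foot, shank, thigh = (link_poses[f"{side}-{s}"] for s in ("F", "S", "T"))
        ankle = joint_trajectories[f"{side}-A"]
        knee = joint_trajectories[f"{side}-K"]
        hip = joint_trajectories[f"{side}-H"]
        f_ankle, t_ankle = newton_euler_link(
            params.m_foot, params.i_foot, foot.origins, foot.angles, ankle, grid,
            f_ext=grf.forces[side], r_ext=grf.cops[side], fit_order=fit_order,
        )
        f_knee, t_knee = newton_euler_link(
            params.m_shank, params.i_shank, shank.origins, shank.angles, knee, grid,
            dist=ankle, f_dist=-f_ankle, t_dist=-t_ankle, fit_order=fit_order,
        )
        _, t_hip = newton_euler_link(
            params.m_thigh, params.i_thigh, thigh.origins, thigh.angles, hip, grid,
            dist=knee, f_dist=-f_knee, t_dist=-t_knee, fit_order=fit_order,
        )
        # clockwise-positive reporting, matching the angle convention
        torques[f"{side}-A"] = -t_ankle
        torques[f"{side}-K"] = -t_knee
        torques[f"{side}-H"] = -t_hip
    return torques


@dataclass
class EvaluationReport:
    """Angle, torque and link-length comparison between truth and an estimate."""

    angle_errors: dict[str, dict[str, float]]
    torque_errors: dict[str, dict[str, float]]
    lengths: dict[str, dict[str, float]]

    def max_angle_error(self) -> float:
        return max(v["max_abs"] for v in self.angle_errors.values())

    def max_torque_error(self) -> float:
        return max(v["max_abs"] for v in self.torque_errors.values())

    def as_dict(self) -> dict:
        return {
            "angle_errors": self.angle_errors,
            "torque_errors": self.torque_errors,
            "lengths": self.lengths,
        }


def _error_summary(diff: np.ndarray) -> dict[str, float]:
    return {
        "max_abs": float(np.abs(diff).max()),
        "rms": float(np.sqrt(np.mean(diff**2))),
    }


def evaluate_assimilation(
    true_angles: dict[str, np.ndarray],
    true_torques: dict[str, np.ndarray],
    est_angles: dict[str, np.ndarray],
    est_torques: dict[str, np.ndarray],
    est_lengths: dict[str, np.ndarray] | None = None,
) -> EvaluationReport:
    """Machine-readable error report of an assimilated motion against truth.

    Angle entries cover every series present in both dictionaries (the six
    joints and the HAT tilt); torque entries likewise; ``est_lengths`` adds
    per-link estimated length mean and range over the cycle.
    """
    angle_errors = {
        key: _error_summary(est_angles[key] - true_angles[key])
        for key in true_angles
        if key in est_angles
    }
    torque_errors = {
        key: _error_summary(est_torques[key] - true_torques[key])
        for key in true_torques
        if key in est_torques
    }
    lengths = {}
    for name, series in (est_lengths or {}).items():
        lengths[name] = {
            "mean": float(np.mean(series)),
            "range": float(np.max(series) - np.min(series)),
        }
    return EvaluationReport(angle_errors, torque_errors, lengths)
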