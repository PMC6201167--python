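"""The naive joint-constraint baseline.

The naive algorithm treats the STA-affected marker frames as if they were
rigidly fixed to the links: for every pin joint it finds the pair of constant
local joint positions that best satisfies the joint constraint on those
frames, and estimates each global joint trajectory as the midpoint of the two
links' predictions.  It removes no STA — it is deliberately the uncorrected
baseline — but its outputs provide the initialization for the periodic
algorithm.

The joint-constraint cost is written in the literature as a sum of residual
norms; it is minimized here as a sum of *squared* norms, which makes every
solve an exact linear least-squares problem.  Both cost values are reported in
the result diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMotionError
from .fourier import FourierCoeffs2D, fit_series
from .frames import (
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
    compose,
    joint_angles,
    joint_residual,
    marker_frames,
    to_global,
    to_local,
)
from .results import AssimilationResult, ShapeParams

__all__ = ["estimate_constant_joints", "naive_assimilate", "naive_sta_init", "StaInit"]


def estimate_constant_joints(
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    frames: dict[str, PoseSeries] | None = None,
) -> tuple[dict[tuple[str, str], np.ndarray], dict]:
    """Constant local joint positions minimizing the squared joint-constraint cost.

    Returns ``(locals, report)``: locals keyed by ``(link, joint)``; the report
    carries per-joint rank/condition diagnostics and both the squared and the
    summed-norm cost at the optimum.
    """
    frames = frames or marker_frames(markers, topology)
    locals_: dict[tuple[str, str], np.ndarray] = {}
    report: dict = {"joints": {}}
    for joint in topology.joints:
        fa, fb = frames[joint.proximal], frames[joint.distal]
        n = len(fa)
        mat = np.zeros((2 * n, 4))
        mat[:, 0:2] = fa.rotations.reshape(2 * n, 2)
        mat[:, 2:4] = -fb.rotations.reshape(2 * n, 2)
        rhs = (fb.origins - fa.origins).reshape(2 * n)
        sol, _, rank, sv = np.linalg.lstsq(mat, rhs, rcond=None)
        if rank < 4 or sv[-1] < 1e-10 * sv[0]:
            raise DegenerateMotionError(
                f"joint {joint.name!r}: insufficient relative rotation between "
                f"{joint.proximal!r} and {joint.distal!r} to determine the joint "
                f"position (rank={rank})"
            )
        ja, jb = sol[0:2], sol[2:4]
        locals_[(joint.proximal, joint.name)] = ja
        locals_[(joint.distal, joint.name)] = jb
        res, cost_sum = joint_residual(fa, fb, ja, jb)
        report["joints"][joint.name] = {
            "rank": int(rank),
            "condition": float(sv[0] / sv[-1]),
            "cost_squared": float(np.sum(res**2)),
            "cost_sum_norm": cost_sum,
        }
    report["cost_squared"] = float(
        sum(j["cost_squared"] for j in report["joints"].values())
    )
    report["cost_sum_norm"] = float(
        sum(j["cost_sum_norm"] for j in report["joints"].values())
    )
    return locals_, report


def link_length_series(
    topology: LinkageTopology,
    link_frames: dict[str, PoseSeries],
    joint_trajectories: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Estimated link length over the cycle.

    For a link spanning two joints (one as distal, one as proximal — thighs
    and shanks) this is the distance between the two estimated joint
    trajectories; otherwise (HAT, feet) the mean distance from the link-frame
    origin (the CoM) to its associated joint(s).
    """
    out = {}
    for name in topology.links:
        incident = topology.joints_of(name)
        prox = [j for j in incident if j.distal == name]
        dist = [j for j in incident if j.proximal == name]
        if prox and dist:
            out[name] = np.linalg.norm(
                joint_trajectories[dist[0].name] - joint_trajectories[prox[0].name],
                axis=1,
            )
        else:
            dists = [
                np.linalg.norm(joint_trajectories[j.name] - link_frames[name].origins, axis=1)
                for j in incident
            ]
            out[name] = np.mean(dists, axis=0)
    return out


def naive_assimilate(
    markers: MarkerTrajectorySet, topology: LinkageTopology
) -> AssimilationResult:
    """Run the naive baseline end to end.

    Marker frames stand in for the landmark frames; each joint trajectory is
    the midpoint of the two adjacent links' predictions; link frames and joint
    angles follow from the topology's landmark geometry.  The STA fields of
    the result are empty — the naive method does not estimate STA.
    """
    markers.check_topology(topology)
    frames = marker_frames(markers, topology)
    locals_, report = estimate_constant_joints(markers, topology, frames)
    trajectories = {}
    for joint in topology.joints:
        pa = to_global(frames[joint.proximal], locals_[(joint.proximal, joint.name)])
        pb = to_global(frames[joint.distal], locals_[(joint.distal, joint.name)])
        trajectories[joint.name] = 0.5 * (pa + pb)
    link_frames = {
        name: compose(frames[name], topology.link_frame_in_landmark(name))
        for name in topology.links
    }
    angles = joint_angles(link_frames, topology)
    lengths = link_length_series(topology, link_frames, trajectories)
    report["method"] = "naive"
    return AssimilationResult(
        landmark_frames=frames,
        link_frames=link_frames,
        joint_locals=locals_,
        joint_trajectories=trajectories,
        joint_angles=angles,
        link_lengths=lengths,
        report=report,
    )


@dataclass
class StaInit:
    """Rough per-link STA initialization extracted by the naive algorithm.

    ``q1``/``q2`` are order-K Fourier fits of each marker's mean-subtracted
    excursion; ``shape`` packs the initial inter-landmark distance (the mean
    inter-marker distance) and coefficient differences.  ``tilt_estimate`` is
    an approximate marker-frame tilt series obtained by comparing the marker
    axis with a joint-based axis; it is ``None`` when the naive joint geometry
    offers no usable lever arm, and is used only to rank candidate solutions
    of the shape system.

    Note an identifiability fact: in a link's *own* marker frame the two
    markers sit on the x-axis by construction, so the transverse (y)
    components of ``q1``/``q2`` extracted this way are identically zero — the
    transverse artifact enters the observable marker data only at second
    order, which is why the shape identification is a quadratic problem.
    """

    link: str
    q1: FourierCoeffs2D
    q2: FourierCoeffs2D
    shape: ShapeParams
    tilt_estimate: np.ndarray | None = None


def _mean_subtracted_angle(raw: np.ndarray) -> np.ndarray:
    unwrapped = np.unwrap(raw)
    return unwrapped - unwrapped.mean()


def naive_sta_init(
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    order: int,
    result: AssimilationResult | None = None,
) -> dict[str, StaInit]:
    """Initial STA estimate without assuming periodicity (then Fourier-fitted).

    Each marker is expressed in its own link's naive marker frame, the cycle
    mean is subtracted (only the zero-mean artifact is identifiable), and the
    residual is fitted with an order-``order`` DC-free Fourier series.  The
    initial inter-landmark distance is the mean inter-marker distance.
    """
    result = result or naive_assimilate(markers, topology)
    grid = markers.grid
    out: dict[str, StaInit] = {}
    for name in topology.links:
        frame = result.landmark_frames[name]
        fits = []
        for j in (1, 2):
            local = to_local(frame, markers.get(name, j))
            fits.append(fit_series(local - local.mean(axis=0), grid, order))
        dist = np.linalg.norm(markers.get(name, 2) - markers.get(name, 1), axis=1)
        shape = ShapeParams(
            float(dist.mean()),
            fits[1].qx - fits[0].qx,
            fits[1].qy - fits[0].qy,
            diagnostics={"source": "naive_init"},
        )
        tilt = _tilt_estimate(name, topology, result, frame)
        out[name] = StaInit(name, fits[0], fits[1], shape, tilt)
    return out


def _tilt_estimate(
    name: str,
    topology: LinkageTopology,
    result: AssimilationResult,
    frame: PoseSeries,
) -> np.ndarray | None:
    """Marker-frame tilt proxy from naive joint trajectories.

    The landmark axis sits at a fixed (unknown) angle from any link-fixed
    axis, so the mean-subtracted difference between the marker-axis angle and
    a joint-based axis angle approximates the tilt of the marker frame
    relative to the landmark frame.
    """
    incident = topology.joints_of(name)
    prox = [j for j in incident if j.distal == name]
    dist = [j for j in incident if j.proximal == name]
    marker_axis = np.arctan2(frame.rotations[:, 1, 0], frame.rotations[:, 0, 0])
    if prox and dist:
        axis = (
            result.joint_trajectories[dist[0].name]
            - result.joint_trajectories[prox[0].name]
        )
    elif incident:
        axis = frame.origins - result.joint_trajectories[incident[0].name]
        lever = np.linalg.norm(axis, axis=1)
        if lever.min() < 0.02:  # m; too short to carry angular information
            return None
    else:
        return None
    axis_angle = np.arctan2(axis[:, 1], axis[:, 0])
    return _mean_subtracted_angle(marker_axis - axis_angle)
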