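"""Planar coordinate frames, the linkage topology, and joint geometry.

Frame conventions follow the marker/landmark construction used throughout the
package: the frame of a point pair ``(p1, p2)`` has its origin at the midpoint
and its x-axis directed from ``p1`` to ``p2``; the y-axis is the x-axis rotated
by +90 degrees, so every rotation is proper.  Rotation matrices are
authoritative; angles are extracted with ``atan2`` from the first column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMotionError, DegeneratePairError, InputError
from .fourier import CycleGrid

__all__ = [
    "PlanarPose",
    "PoseSeries",
    "LinkSpec",
    "JointSpec",
    "LinkageTopology",
    "MarkerTrajectorySet",
    "rotation_matrix",
    "pair_frame",
    "pair_frame_series",
    "marker_frames",
    "to_global",
    "to_local",
    "compose",
    "relative_frame",
    "solve_joint_two_instants",
    "solve_joint_all_instants",
    "joint_residual",
    "joint_angles",
]

ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])


def rotation_matrix(angle: float | np.ndarray) -> np.ndarray:
    """Proper rotation by ``angle`` (radians, counterclockwise positive).

    Vectorizes: an array of ``M`` angles gives an ``(M, 2, 2)`` stack.
    """
    c, s = np.cos(angle), np.sin(angle)
    out = np.empty(np.shape(angle) + (2, 2))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def _check_rotation(rot: np.ndarray, tol: float = 1e-8) -> None:
    err = np.abs(np.swapaxes(rot, -1, -2) @ rot - np.eye(2)).max()
    if err > tol:
        raise InputError(f"rotation is not orthonormal (deviation {err:.2e})")
    if np.any(np.linalg.det(rot) < 0):
        raise InputError("rotation is improper (det = -1)")


@dataclass
class PlanarPose:
    """Origin plus proper rotation: one rigid placement in the plane."""

    origin: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(2, 2)
        _check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "PlanarPose":
        return cls(np.zeros(2), np.eye(2))

    @classmethod
    def from_angle(cls, origin, angle: float) -> "PlanarPose":
        return cls(np.asarray(origin, dtype=float), rotation_matrix(angle))

    @property
    def angle(self) -> float:
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))

    def inverse(self) -> "PlanarPose":
        rt = self.rotation.T
        return PlanarPose(-rt @ self.origin, rt)


@dataclass
class PoseSeries:
    """``N`` planar poses on a cycle grid (origins ``(N,2)``, rotations ``(N,2,2)``)."""

    origins: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.origins.ndim != 2 or self.origins.shape[1] != 2:
            raise InputError(f"origins must be (N, 2), got {self.origins.shape}")
        if self.rotations.shape != (self.origins.shape[0], 2, 2):
            raise InputError(
                f"rotations must be (N, 2, 2) matching origins, got {self.rotations.shape}"
            )
        _check_rotation(self.rotations)

    def __len__(self) -> int:
        return self.origins.shape[0]

    @classmethod
    def from_angles(cls, origins: np.ndarray, angles: np.ndarray) -> "PoseSeries":
        return cls(np.asarray(origins, dtype=float), rotation_matrix(np.asarray(angles)))

    def pose(self, n: int) -> PlanarPose:
        """Single pose at 0-based sample index ``n``."""
        return PlanarPose(self.origins[n], self.rotations[n])

    @property
    def angles(self) -> np.ndarray:
        """Frame angles, continuous over the cycle (unwrapped, mean in (-pi, pi])."""
        raw = np.unwrap(np.arctan2(self.rotations[:, 1, 0], self.rotations[:, 0, 0]))
        return raw - 2.0 * np.pi * np.round(np.mean(raw) / (2.0 * np.pi))

    def transformed(self, by: PlanarPose) -> "PoseSeries":
        """Apply one global rigid motion to every pose."""
        return PoseSeries(
            self.origins @ by.rotation.T + by.origin, by.rotation @ self.rotations
        )


# ---------------------------------------------------------------------------
# Topology


@dataclass
class LinkSpec:
    """One rigid link with exactly two marker/landmark slots.

    ``landmarks_local`` (optional, fixtures and evaluation) holds the two
    landmark positions in the link frame, rows = landmark 1 and 2.  When
    present it fixes the constant transform between the landmark frame and the
    link frame, used to reconstruct link-coordinate kinematics.
    """

    name: str
    landmarks_local: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.landmarks_local is not None:
            self.landmarks_local = np.asarray(self.landmarks_local, dtype=float).reshape(2, 2)


@dataclass
class JointSpec:
    """Pin joint between a proximal and a distal link.

    ``angle_offset`` is added to the raw relative frame angle so the joint
    angle is zero at the model's reference posture.
    """

    name: str
    proximal: str
    distal: str
    angle_offset: float = 0.0


@dataclass
class LinkageTopology:
    """Links, joints and angle conventions of a planar multi-rigid-link model."""

    links: dict[str, LinkSpec]
    joints: list[JointSpec]
    root: str | None = None
    root_angle_offset: float = 0.0

    def __post_init__(self) -> None:
        for j in self.joints:
            if j.proximal not in self.links or j.distal not in self.links:
                raise InputError(f"joint {j.name} references unknown link")
            if j.proximal == j.distal:
                raise InputError(f"joint {j.name} connects a link to itself")
        if self.root is not None and self.root not in self.links:
            raise InputError(f"root link {self.root!r} unknown")
        if self.links and self.joints and not self._connected():
            raise InputError("joint graph is not connected")

    def _connected(self) -> bool:
        names = list(self.links)
        seen = {names[0]}
        frontier = [names[0]]
        adj: dict[str, list[str]] = {n: [] for n in names}
        for j in self.joints:
            adj[j.proximal].append(j.distal)
            adj[j.distal].append(j.proximal)
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        return len(seen) == len(names)

    def marker_slots(self) -> list[tuple[str, int]]:
        """Ordered (link, marker index) pairs; defines matrix column order."""
        return [(name, j) for name in self.links for j in (1, 2)]

    def joints_of(self, link: str) -> list[JointSpec]:
        return [j for j in self.joints if link in (j.proximal, j.distal)]

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise InputError(f"unknown joint {name!r}")

    def landmark_frame_in_link(self, link: str) -> PlanarPose:
        """Constant pose of the landmark frame expressed in the link frame."""
        spec = self.links[link]
        if spec.landmarks_local is None:
            return PlanarPose.identity()
        return pair_frame(spec.landmarks_local[0], spec.landmarks_local[1])

    def link_frame_in_landmark(self, link: str) -> PlanarPose:
        """Constant pose of the link frame expressed in the landmark frame."""
        return self.landmark_frame_in_link(link).inverse()


@dataclass
class MarkerTrajectorySet:
    """Global 2-D marker position series over one cycle, two markers per link."""

    positions: dict[tuple[str, int], np.ndarray]
    grid: CycleGrid

    def __post_init__(self) -> None:
        for key, arr in self.positions.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.n_samples, 2):
                raise InputError(
                    f"marker {key} has shape {arr.shape}, expected "
                    f"({self.grid.n_samples}, 2)"
                )
            if not np.all(np.isfinite(arr)):
                raise InputError(f"marker {key} contains non-finite coordinates")
            self.positions[key] = arr

    def get(self, link: str, j: int) -> np.ndarray:
        try:
            return self.positions[(link, j)]
        except KeyError:
            raise InputError(f"missing marker trajectory for ({link!r}, {j})") from None

    def check_topology(self, topology: LinkageTopology) -> None:
        for slot in topology.marker_slots():
            if slot not in self.positions:
                raise InputError(f"marker set lacks trajectory for slot {slot}")

    def as_matrix(self, topology: LinkageTopology) -> np.ndarray:
        """``(N, 2M)`` matrix, columns ``[x, y]`` per slot in topology order."""
        self.check_topology(topology)
        return np.hstack([self.positions[s] for s in topology.marker_slots()])

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, topology: LinkageTopology, grid: CycleGrid
    ) -> "MarkerTrajectorySet":
        matrix = np.asarray(matrix, dtype=float)
        slots = topology.marker_slots()
        if matrix.ndim != 2 or matrix.shape[1] != 2 * len(slots):
            raise InputError(
                f"marker matrix must be (N, {2 * len(slots)}), got {matrix.shape}"
            )
        positions = {
            slot: matrix[:, 2 * i : 2 * i + 2] for i, slot in enumerate(slots)
        }
        return cls(positions, grid)

    def transformed(self, by: PlanarPose) -> "MarkerTrajectorySet":
        """Apply one global rigid motion to every marker trajectory."""
        return MarkerTrajectorySet(
            {k: v @ by.rotation.T + by.origin for k, v in self.positions.items()},
            self.grid,
        )


# ---------------------------------------------------------------------------
# Frame constructions and transforms


def pair_frame(p1, p2, eps: float = 1e-9, context: str = "") -> PlanarPose:
    """Frame of a point pair: origin at the midpoint, x-axis from p1 to p2."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    diff = p2 - p1
    norm = np.linalg.norm(diff)
    if norm <= eps:
        where = f" ({context})" if context else ""
        raise DegeneratePairError(
            f"point pair coincides within {eps:g} m{where}; frame undefined"
        )
    xaxis = diff / norm
    rot = np.column_stack([xaxis, ROT90 @ xaxis])
    return PlanarPose((p1 + p2) / 2.0, rot)


def pair_frame_series(
    p1: np.ndarray, p2: np.ndarray, eps: float = 1e-9, context: str = ""
) -> PoseSeries:
    """Vectorized :func:`pair_frame` over ``(N, 2)`` trajectories."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    diff = p2 - p1
    norm = np.linalg.norm(diff, axis=1)
    bad = np.nonzero(norm <= eps)[0]
    if bad.size:
        where = f" ({context})" if context else ""
        raise DegeneratePairError(
            f"point pair coincides within {eps:g} m at sample {bad[0] + 1}{where}"
        )
    xaxis = diff / norm[:, None]
    rot = np.empty((p1.shape[0], 2, 2))
    rot[:, :, 0] = xaxis
    rot[:, :, 1] = xaxis @ ROT90.T
    return PoseSeries((p1 + p2) / 2.0, rot)


def marker_frames(
    markers: MarkerTrajectorySet, topology: LinkageTopology
) -> dict[str, PoseSeries]:
    """Marker-coordinate frames of every link, built from the raw markers."""
    markers.check_topology(topology)
    return {
        name: pair_frame_series(
            markers.get(name, 1), markers.get(name, 2), context=f"link {name}"
        )
        for name in topology.links
    }


def to_global(pose: PlanarPose | PoseSeries, local: np.ndarray) -> np.ndarray:
    """Map local coordinates into the parent frame: ``origin + R @ local``.

    ``local`` may be a single point ``(2,)`` or a series ``(N, 2)`` matching a
    :class:`PoseSeries`.
    """
    local = np.asarray(local, dtype=float)
    if isinstance(pose, PlanarPose):
        return pose.origin + local @ pose.rotation.T
    if local.ndim == 1:
        local = np.broadcast_to(local, (len(pose), 2))
    return pose.origins + np.einsum("nij,nj->ni", pose.rotations, local)


def to_local(pose: PlanarPose | PoseSeries, global_pt: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`to_global`."""
    global_pt = np.asarray(global_pt, dtype=float)
    if isinstance(pose, PlanarPose):
        return (global_pt - pose.origin) @ pose.rotation
    if global_pt.ndim == 1:
        global_pt = np.broadcast_to(global_pt, (len(pose), 2))
    return np.einsum("nji,nj->ni", pose.rotations, global_pt - pose.origins)


def compose(parent, child):
    """Pose of ``child`` (expressed in ``parent``) in the parent's parent frame.

    Implements ``o = o_p + A_p o_c`` and ``A = A_p A_c``; accepts any mix of
    :class:`PlanarPose` and :class:`PoseSeries` (series broadcast elementwise).
    """
    if isinstance(parent, PlanarPose) and isinstance(child, PlanarPose):
        return PlanarPose(
            parent.origin + parent.rotation @ child.origin,
            parent.rotation @ child.rotation,
        )
    if isinstance(parent, PoseSeries) and isinstance(child, PlanarPose):
        return PoseSeries(to_global(parent, child.origin), parent.rotations @ child.rotation)
    if isinstance(parent, PlanarPose) and isinstance(child, PoseSeries):
        return child.transformed(parent)
    return PoseSeries(
        to_global(parent, child.origins), parent.rotations @ child.rotations
    )


def relative_frame(child, parent):
    """Pose of ``child`` expressed in ``parent`` (both given in a common frame)."""
    if isinstance(child, PlanarPose) and isinstance(parent, PlanarPose):
        return compose(parent.inverse(), child)
    if isinstance(child, PoseSeries) and isinstance(parent, PoseSeries):
        rot_t = np.swapaxes(parent.rotations, 1, 2)
        return PoseSeries(to_local(parent, child.origins), rot_t @ child.rotations)
    raise InputError("relative_frame needs two poses or two series")


# ---------------------------------------------------------------------------
# Joints


def solve_joint_two_instants(
    frames_a: PoseSeries,
    frames_b: PoseSeries,
    n1: int,
    n2: int,
    cond_threshold: float = 1e8,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant local joint positions from the joint constraint at two instants.

    Solves the stacked 4x4 system built from the two frames at (0-based)
    samples ``n1`` and ``n2``; valid when the relative rotation between the
    links differs between the instants.
    """
    if n1 == n2:
        raise InputError("two-instant solve needs two distinct samples")
    mat = np.zeros((4, 4))
    rhs = np.zeros(4)
    for row, n in enumerate((n1, n2)):
        mat[2 * row : 2 * row + 2, 0:2] = frames_a.rotations[n]
        mat[2 * row : 2 * row + 2, 2:4] = -frames_b.rotations[n]
        rhs[2 * row : 2 * row + 2] = frames_b.origins[n] - frames_a.origins[n]
    cond = np.linalg.cond(mat)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise DegenerateMotionError(
            f"relative rotation at samples {n1 + 1} and {n2 + 1} is (nearly) "
            f"identical; joint position indeterminate (cond={cond:.2e})"
        )
    sol = np.linalg.solve(mat, rhs)
    return sol[0:2], sol[2:4]


def solve_joint_all_instants(
    frames_a: PoseSeries, frames_b: PoseSeries, min_rank: int = 4
) -> tuple[np.ndarray, np.ndarray, dict]:
    """All-samples least-squares generalization of the two-instant solve.

    Minimizes the summed squared joint-constraint residual over the whole
    cycle; agrees with the two-instant solve on noise-free rigid data.
    """
    n = len(frames_a)
    if len(frames_b) != n:
        raise InputError("frame series lengths differ")
    mat = np.zeros((2 * n, 4))
    mat[:, 0:2] = frames_a.rotations.reshape(2 * n, 2)
    mat[:, 2:4] = -frames_b.rotations.reshape(2 * n, 2)
    rhs = (frames_b.origins - frames_a.origins).reshape(2 * n)
    sol, res, rank, sv = np.linalg.lstsq(mat, rhs, rcond=None)
    if rank < min_rank or sv[-1] < 1e-10 * sv[0]:
        raise DegenerateMotionError(
            "insufficient relative rotation over the cycle; joint position "
            f"indeterminate (rank={rank})"
        )
    report = {"rank": int(rank), "condition": float(sv[0] / sv[-1])}
    return sol[0:2], sol[2:4], report


def joint_residual(
    frames_a: PoseSeries,
    frames_b: PoseSeries,
    j_a_local: np.ndarray,
    j_b_local: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-sample joint-constraint residual and its summed Euclidean norm."""
    res = to_global(frames_a, np.asarray(j_a_local, float)) - to_global(
        frames_b, np.asarray(j_b_local, float)
    )
    return res, float(np.linalg.norm(res, axis=1).sum())


def joint_angles(
    poses: dict[str, PoseSeries], topology: LinkageTopology
) -> dict[str, np.ndarray]:
    """Joint angle series plus the root link's absolute tilt.

    Each joint angle is the distal link's frame angle relative to the proximal
    link, sign-flipped so a clockwise rotation is positive, plus the joint's
    reference offset; the root entry (under the root link's name) is the tilt
    of the root link from the vertical axis, clockwise positive.  All series
    are unwrapped to be continuous over the cycle.
    """
    phi = {}
    for name in topology.links:
        if name not in poses:
            raise InputError(f"pose series missing for link {name!r}")
        phi[name] = poses[name].angles
    out: dict[str, np.ndarray] = {}
    for j in topology.joints:
        raw = phi[j.proximal] - phi[j.distal] + j.angle_offset
        out[j.name] = raw - 2.0 * np.pi * np.round(np.mean(raw) / (2.0 * np.pi))
    if topology.root is not None:
        raw = -phi[topology.root] - topology.root_angle_offset
        out[topology.root] = raw - 2.0 * np.pi * np.round(np.mean(raw) / (2.0 * np.pi))
    return out
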