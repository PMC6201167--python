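"""Synthetic seven-link planar gait fixture.

Generates exactly-rigid, exactly-periodic sagittal-plane walking kinematics for
a head-arms-trunk (HAT) link, two thighs, two shanks and two feet connected by
pin joints, places two landmarks per link (14 in total), injects seeded
periodic soft-tissue artifact (STA) on the markers, and supplies a synthetic
ground-reaction force (GRF) for inverse-dynamics comparisons.

The walking motion is prescribed as band-limited periodic joint-angle
trajectories with gait-like ranges, viewed in the frame co-moving with the
average progression velocity (an inertial frame, so dynamics are unaffected);
a forward-dynamics controller is deliberately not part of the fixture — the
assimilation algorithms consume kinematics only.

All randomness flows through explicit seeds: identical seeds give
bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .fourier import CycleGrid, FourierCoeffs2D, eval_series
from .frames import (
    JointSpec,
    LinkSpec,
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
    compose,
    to_global,
)

__all__ = [
    "GaitModelParams",
    "GaitOptions",
    "GaitKinematics",
    "StaProfileSet",
    "GroundReaction",
    "SUBJECT_SEEDS",
    "build_topology",
    "generate_true_kinematics",
    "landmark_frames",
    "landmark_trajectories",
    "generate_sta_profiles",
    "inject_sta",
    "generate_grf",
    "simulate_fixture",
]

#: Seven seed presets standing in for the seven motion-captured subjects.
SUBJECT_SEEDS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)

GRAVITY = 9.81

LEFT_LINKS = ("l-T", "l-S", "l-F")
RIGHT_LINKS = ("r-T", "r-S", "r-F")
ALL_LINKS = ("HAT",) + LEFT_LINKS + RIGHT_LINKS


@dataclass(frozen=True)
class GaitModelParams:
    """Body-segment parameters of the rigid seven-link model.

    Masses in kg, lengths/offsets in m, moments of inertia about the segment
    CoM in kg*m^2.  ``d_*`` offsets locate the CoM relative to the named joint
    along the segment axis.
    """

    m_hat: float = 40.548
    m_thigh: float = 6.882
    m_shank: float = 3.162
    m_foot: float = 0.682
    l_hat: float = 0.536
    l_thigh: float = 0.420
    l_shank: float = 0.379
    l_foot: float = 0.122
    d_hat_hip: float = 0.204
    d_hip_thigh: float = 0.200
    d_knee_shank: float = 0.154
    d_ankle_foot: float = 0.050
    d_ankle_heel: float = 0.079
    i_hat: float = 1.09933
    i_thigh: float = 0.09485
    i_shank: float = 0.03001
    i_foot: float = 0.00014

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise InputError(f"gait parameter {name} must be positive, got {value}")

    @property
    def total_mass(self) -> float:
        return self.m_hat + 2.0 * (self.m_thigh + self.m_shank + self.m_foot)

    def link_mass(self, link: str) -> float:
        return {"HAT": self.m_hat, "T": self.m_thigh, "S": self.m_shank, "F": self.m_foot}[
            link.split("-")[-1]
        ]

    def link_inertia(self, link: str) -> float:
        return {"HAT": self.i_hat, "T": self.i_thigh, "S": self.i_shank, "F": self.i_foot}[
            link.split("-")[-1]
        ]


@dataclass(frozen=True)
class GaitOptions:
    """Tunables of the prescribed gait pattern.

    Angle amplitudes are in radians; the prescribed trajectories stay within
    the gait-like ranges hip +-0.35, knee 0..1.1, ankle +-0.3, HAT tilt
    +-0.05.  ``stance_fraction`` is the fraction of the cycle each foot is
    loaded; the two legs are half a cycle out of phase.
    """

    hip_cos: float = 0.28
    hip_sin: float = 0.06
    hip_sin2: float = 0.04
    knee_mean: float = 0.55
    knee_cos: float = 0.40
    knee_phase: float = 0.40
    knee_sin2: float = 0.10
    ankle_cos: float = 0.10
    ankle_sin2: float = 0.12
    ankle_cos2: float = 0.05
    hat_cos: float = 0.015
    hat_sin2: float = 0.030
    sway_x: float = 0.030
    bob_y: float = 0.015
    pelvis_height: float = 1.0
    stance_fraction: float = 0.62
    grf_second_hump: float = 0.8
    grf_shear: float = 0.12


@dataclass
class GaitKinematics:
    """True (STA-free) kinematics of the fixture."""

    grid: CycleGrid
    link_poses: dict[str, PoseSeries]
    joint_trajectories: dict[str, np.ndarray]
    angles: dict[str, np.ndarray]  # six joints plus the HAT tilt under "HAT"


@dataclass
class StaProfileSet:
    """Per-marker STA Fourier coefficients (zero-mean, order K)."""

    profiles: dict[tuple[str, int], FourierCoeffs2D]
    seed: int
    amplitude: float
    order: int = 4


@dataclass
class GroundReaction:
    """Per-foot force (N), center of pressure (m) and stance masks."""

    forces: dict[str, np.ndarray]
    cops: dict[str, np.ndarray]
    stance: dict[str, np.ndarray]


def build_topology(params: GaitModelParams | None = None) -> LinkageTopology:
    """Seven-link topology with landmark geometry in CoM-anchored link frames.

    Each link frame has its origin at the segment CoM and its x-axis toward the
    distal end (for HAT, toward the hip).  Landmarks sit at anatomical-landmark
    stand-ins: HAT carries C7-like and xiphoid-like points, thighs span hip to
    knee (greater trochanter to lateral femoral condyle), shanks knee to ankle
    (lateral tibial condyle to lateral malleolus), feet heel to metatarsal.
    """
    p = params or GaitModelParams()
    hat_top = -(p.l_hat - p.d_hat_hip)
    links = {
        "HAT": LinkSpec("HAT", [[hat_top, 0.0], [hat_top + 0.30, 0.0]]),
    }
    for side in ("l", "r"):
        links[f"{side}-T"] = LinkSpec(
            f"{side}-T", [[-p.d_hip_thigh, 0.0], [p.l_thigh - p.d_hip_thigh, 0.0]]
        )
        links[f"{side}-S"] = LinkSpec(
            f"{side}-S", [[-p.d_knee_shank, 0.0], [p.l_shank - p.d_knee_shank, 0.0]]
        )
        heel = -p.d_ankle_foot - p.d_ankle_heel
        links[f"{side}-F"] = LinkSpec(
            f"{side}-F", [[heel, 0.0], [heel + p.l_foot, 0.0]]
        )
    joints = []
    for side in ("l", "r"):
        joints += [
            JointSpec(f"{side}-H", "HAT", f"{side}-T"),
            JointSpec(f"{side}-K", f"{side}-T", f"{side}-S"),
            JointSpec(f"{side}-A", f"{side}-S", f"{side}-F", angle_offset=np.pi / 2),
        ]
    return LinkageTopology(links, joints, root="HAT", root_angle_offset=np.pi / 2)


def _prescribed_angles(grid: CycleGrid, opt: GaitOptions) -> dict[str, np.ndarray]:
    phi = grid.phases
    out: dict[str, np.ndarray] = {
        "HAT": opt.hat_cos * np.cos(phi) + opt.hat_sin2 * np.sin(2 * phi)
    }
    for side, shift in (("l", 0.0), ("r", np.pi)):
        ph = phi + shift
        out[f"{side}-H"] = (
            opt.hip_cos * np.cos(ph) + opt.hip_sin * np.sin(ph) + opt.hip_sin2 * np.sin(2 * ph)
        )
        out[f"{side}-K"] = (
            opt.knee_mean
            - opt.knee_cos * np.cos(ph - opt.knee_phase)
            + opt.knee_sin2 * np.sin(2 * ph)
        )
        out[f"{side}-A"] = (
            opt.ankle_cos * np.cos(ph)
            + opt.ankle_sin2 * np.sin(2 * ph)
            + opt.ankle_cos2 * np.cos(2 * ph)
        )
    return out


def generate_true_kinematics(
    params: GaitModelParams | None = None,
    grid: CycleGrid | None = None,
    options: GaitOptions | None = None,
) -> GaitKinematics:
    """Forward kinematics of the prescribed periodic gait.

    Returns CoM-anchored link poses, global joint trajectories and the
    prescribed angle series.  Joint-to-joint distances are constant and equal
    to the segment lengths at every sample (exactly rigid motion), and the
    cycle closes periodically because every prescribed series is a low-order
    Fourier polynomial of the cycle phase.
    """
    params = params or GaitModelParams()
    grid = grid or CycleGrid(200, duration=1.0)
    opt = options or GaitOptions()
    ang = _prescribed_angles(grid, opt)
    if np.any(ang["l-K"] <= 0.0) or np.any(ang["r-K"] <= 0.0) or np.any(
        np.abs(ang["l-H"]) > np.pi / 2
    ):
        raise InputError("gait options produce a self-crossing (degenerate) posture")
    phi = grid.phases
    hat_com = np.column_stack(
        [opt.sway_x * np.sin(phi), opt.pelvis_height + opt.bob_y * np.cos(2 * phi)]
    )
    # psi: clockwise tilt of each segment from its reference direction
    psi = {"HAT": ang["HAT"]}
    for side in ("l", "r"):
        psi[f"{side}-T"] = psi["HAT"] + ang[f"{side}-H"]
        psi[f"{side}-S"] = psi[f"{side}-T"] + ang[f"{side}-K"]
        psi[f"{side}-F"] = psi[f"{side}-S"] + ang[f"{side}-A"]

    def down(a):  # unit vector of a leg segment tilted clockwise by a, ref straight down
        return np.column_stack([-np.sin(a), -np.cos(a)])

    def fwd(a):  # unit vector of the foot axis tilted clockwise by a, ref forward
        return np.column_stack([np.cos(a), -np.sin(a)])

    hip = hat_com + params.d_hat_hip * down(psi["HAT"])
    joints: dict[str, np.ndarray] = {}
    coms = {"HAT": hat_com}
    for side in ("l", "r"):
        knee = hip + params.l_thigh * down(psi[f"{side}-T"])
        ankle = knee + params.l_shank * down(psi[f"{side}-S"])
        joints[f"{side}-H"] = hip
        joints[f"{side}-K"] = knee
        joints[f"{side}-A"] = ankle
        coms[f"{side}-T"] = hip + params.d_hip_thigh * down(psi[f"{side}-T"])
        coms[f"{side}-S"] = knee + params.d_knee_shank * down(psi[f"{side}-S"])
        coms[f"{side}-F"] = ankle + params.d_ankle_foot * fwd(psi[f"{side}-F"])
    # link-frame angles (CCW, global): x-axis CoM->distal
    poses = {}
    for name in ALL_LINKS:
        frame_angle = -psi[name] if name.endswith("F") else -np.pi / 2 - psi[name]
        poses[name] = PoseSeries.from_angles(coms[name], frame_angle)
    return GaitKinematics(grid, poses, joints, ang)


def landmark_frames(
    kin: GaitKinematics | dict[str, PoseSeries], topology: LinkageTopology
) -> dict[str, PoseSeries]:
    """Landmark-coordinate frames implied by link poses and landmark geometry."""
    poses = kin.link_poses if isinstance(kin, GaitKinematics) else kin
    return {
        name: compose(poses[name], topology.landmark_frame_in_link(name))
        for name in topology.links
    }


def landmark_trajectories(
    kin: GaitKinematics | dict[str, PoseSeries],
    topology: LinkageTopology,
    grid: CycleGrid | None = None,
) -> MarkerTrajectorySet:
    """Noise-free landmark-marker trajectories (the unobservable ground truth)."""
    poses = kin.link_poses if isinstance(kin, GaitKinematics) else kin
    grid = kin.grid if isinstance(kin, GaitKinematics) else grid
    if grid is None:
        raise InputError("grid required when passing raw pose dictionaries")
    positions = {}
    for name, spec in topology.links.items():
        if spec.landmarks_local is None:
            raise InputError(f"link {name!r} has no landmark geometry")
        for j in (1, 2):
            positions[(name, j)] = to_global(poses[name], spec.landmarks_local[j - 1])
    return MarkerTrajectorySet(positions, grid)


def generate_sta_profiles(
    seed: int,
    amplitude: float = 0.01,
    order: int = 4,
    topology: LinkageTopology | None = None,
) -> StaProfileSet:
    """Seeded pseudo-random STA Fourier coefficients for every marker.

    Coefficients are drawn uniformly in ``+-amplitude`` with a ``1/k``
    harmonic decay, per marker and axis — the millimeter-to-centimeter scale
    and low-pass character reported for skin-marker artifact during gait.
    """
    if amplitude < 0:
        raise InputError(f"STA amplitude must be non-negative, got {amplitude}")
    topology = topology or build_topology()
    rng = np.random.default_rng(seed)
    decay = np.tile(1.0 / np.arange(1, order + 1), 2)  # cos block then sin block
    profiles = {}
    for slot in topology.marker_slots():
        qx = rng.uniform(-amplitude, amplitude, 2 * order) * decay
        qy = rng.uniform(-amplitude, amplitude, 2 * order) * decay
        profiles[slot] = FourierCoeffs2D(order, qx, qy)
    return StaProfileSet(profiles, seed=seed, amplitude=amplitude, order=order)


def inject_sta(
    landmarks: MarkerTrajectorySet,
    frames: dict[str, PoseSeries],
    profiles: StaProfileSet,
    grid: CycleGrid | None = None,
) -> MarkerTrajectorySet:
    """Simulated STA-affected markers: add each artifact in its landmark frame.

    ``m_ij[n] = o_i[n] + A_i[n] (m_local_ij + e_ij[n])`` with ``e`` the
    evaluated Fourier STA and ``(o_i, A_i)`` the landmark frames — i.e. the
    artifact rides on the link and is rotated out into the global frame.
    """
    grid = grid or landmarks.grid
    positions = {}
    for (name, j), clean in landmarks.positions.items():
        prof = profiles.profiles.get((name, j))
        if prof is None:
            raise InputError(f"no STA profile for marker ({name!r}, {j})")
        e = eval_series(prof, grid)
        positions[(name, j)] = clean + np.einsum("nij,nj->ni", frames[name].rotations, e)
    return MarkerTrajectorySet(positions, grid)


def generate_grf(
    grid: CycleGrid,
    params: GaitModelParams | None = None,
    options: GaitOptions | None = None,
    kinematics: GaitKinematics | None = None,
    topology: LinkageTopology | None = None,
) -> GroundReaction:
    """Smooth periodic per-foot ground reaction with heel-to-toe CoP progression.

    The vertical force is a double-hump profile, exactly zero in swing, with
    the two feet half a cycle out of phase and the cycle-mean total equal to
    body weight by construction; a small anterior-posterior shear is added.
    The same GRF is fed to the true and the assimilated inverse dynamics, so
    torque *differences* are GRF-independent.
    """
    params = params or GaitModelParams()
    opt = options or GaitOptions()
    if not 0.0 < opt.stance_fraction < 1.0:
        raise InputError("stance fraction must lie in (0, 1)")
    u = np.arange(1, grid.n_samples + 1) / grid.n_samples
    weight = params.total_mass * GRAVITY
    # cycle-mean of sin^2 windows over stance is 1/2 -> normalize to body weight
    amp = weight / (
        2.0 * opt.stance_fraction * 0.5 * (1.0 + opt.grf_second_hump)
    )
    forces, cops, stance = {}, {}, {}
    for side, start in (("l", 0.0), ("r", 0.5)):
        s = np.mod(u - start, 1.0) / opt.stance_fraction
        on = s < 1.0
        s = np.where(on, s, 0.0)
        fy = amp * (np.sin(np.pi * s) ** 2 + opt.grf_second_hump * np.sin(2 * np.pi * s) ** 2)
        fx = -opt.grf_shear * amp * np.sin(2 * np.pi * s) * np.sin(np.pi * s) ** 2
        force = np.column_stack([fx, fy])
        force[~on] = 0.0
        if kinematics is not None:
            topo = topology or build_topology(params)
            foot = kinematics.link_poses[f"{side}-F"]
            lm = topo.links[f"{side}-F"].landmarks_local
            heel = to_global(foot, lm[0])
            toe = to_global(foot, lm[1])
        else:
            heel = np.tile([-params.d_ankle_heel, 0.0], (grid.n_samples, 1))
            toe = np.tile([params.l_foot - params.d_ankle_heel, 0.0], (grid.n_samples, 1))
        cop = (1.0 - s[:, None]) * heel + s[:, None] * toe
        cop[:, 1] = 0.0  # force acts at ground level
        forces[side], cops[side], stance[side] = force, cop, on
    return GroundReaction(forces, cops, stance)


@dataclass
class GaitFixture:
    """One complete synthetic trial: truth, markers, STA, GRF, topology."""

    params: GaitModelParams
    topology: LinkageTopology
    kinematics: GaitKinematics
    landmarks: MarkerTrajectorySet
    markers: MarkerTrajectorySet
    profiles: StaProfileSet
    grf: GroundReaction
    options: GaitOptions = field(default_factory=GaitOptions)


def simulate_fixture(
    seed: int,
    n_samples: int = 200,
    duration: float = 1.0,
    amplitude: float = 0.01,
    order: int = 4,
    params: GaitModelParams | None = None,
    options: GaitOptions | None = None,
) -> GaitFixture:
    """Generate one seeded trial end to end (truth, STA markers, GRF)."""
    params = params or GaitModelParams()
    options = options or GaitOptions()
    grid = CycleGrid(n_samples, duration=duration)
    topology = build_topology(params)
    kin = generate_true_kinematics(params, grid, options)
    frames = landmark_frames(kin, topology)
    landmarks = landmark_trajectories(kin, topology)
    profiles = generate_sta_profiles(seed, amplitude=amplitude, order=order, topology=topology)
    markers = inject_sta(landmarks, frames, profiles, grid)
    grf = generate_grf(grid, params, options, kinematics=kin, topology=topology)
    return GaitFixture(params, topology, kin, landmarks, markers, profiles, grf, options)
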