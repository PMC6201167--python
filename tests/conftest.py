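"""Shared fixtures: the seeded seven-link gait trial and a two-link hinge toy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from stafree import (
    CycleGrid,
    FourierCoeffs2D,
    LinkSpec,
    JointSpec,
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
    simulate_fixture,
    to_global,
)
from stafree.gait import StaProfileSet, inject_sta


@pytest.fixture(scope="session")
def gait_fixture():
    """One seeded seven-link trial at the study conditions (N=200, K=4, 1 cm STA)."""
    return simulate_fixture(seed=1, n_samples=200)


@pytest.fixture(scope="session")
def gait_fixture_clean():
    """Same trial without STA (amplitude 0)."""
    return simulate_fixture(seed=1, n_samples=200, amplitude=0.0)


@dataclass
class TwoLinkToy:
    grid: CycleGrid
    topology: LinkageTopology
    frames: dict[str, PoseSeries]  # true landmark(=link) frames
    landmarks: MarkerTrajectorySet  # noise-free landmark markers
    markers: MarkerTrajectorySet  # STA-affected markers
    profiles: StaProfileSet
    joint_locals: dict[tuple[str, str], np.ndarray]
    joint_global: np.ndarray


def make_two_link(
    n_samples: int = 64,
    order: int = 2,
    amplitude: float = 0.01,
    seed: int = 0,
    c_a: float = 0.4,
    c_b: float = 0.3,
) -> TwoLinkToy:
    """Planar two-link hinge with known geometry and seeded periodic STA.

    Landmarks sit at ``+-C/2`` on each link's own axis, so the landmark frame
    *is* the link frame; the pin joint sits at known constant local positions
    on both links and the hinge angle varies over the cycle.
    """
    grid = CycleGrid(n_samples, duration=1.0)
    phi = grid.phases
    # link A swings moderately; link B articulates relative to A
    ang_a = 0.3 * np.sin(phi) + 0.1 * np.cos(2 * phi)
    ang_b = ang_a + 0.9 + 0.5 * np.cos(phi) + 0.15 * np.sin(2 * phi)
    j_a = np.array([c_a / 2 + 0.05, 0.02])  # joint local, link A landmark frame
    j_b = np.array([-c_b / 2 - 0.04, -0.01])
    origin_a = np.column_stack([0.1 * np.cos(phi), 1.0 + 0.05 * np.sin(2 * phi)])
    frames_a = PoseSeries.from_angles(origin_a, ang_a)
    joint_global = to_global(frames_a, j_a)
    rot_b = PoseSeries.from_angles(np.zeros_like(origin_a), ang_b).rotations
    origin_b = joint_global - np.einsum("nij,j->ni", rot_b, j_b)
    frames_b = PoseSeries(origin_b, rot_b)
    topology = LinkageTopology(
        links={
            "A": LinkSpec("A", [[-c_a / 2, 0.0], [c_a / 2, 0.0]]),
            "B": LinkSpec("B", [[-c_b / 2, 0.0], [c_b / 2, 0.0]]),
        },
        joints=[JointSpec("J", "A", "B")],
        root="A",
    )
    frames = {"A": frames_a, "B": frames_b}
    landmarks = MarkerTrajectorySet(
        {
            (name, j): to_global(frames[name], topology.links[name].landmarks_local[j - 1])
            for name in ("A", "B")
            for j in (1, 2)
        },
        grid,
    )
    rng = np.random.default_rng(seed)
    decay = np.tile(1.0 / np.arange(1, order + 1), 2)
    profiles = StaProfileSet(
        {
            slot: FourierCoeffs2D(
                order,
                rng.uniform(-amplitude, amplitude, 2 * order) * decay,
                rng.uniform(-amplitude, amplitude, 2 * order) * decay,
            )
            for slot in topology.marker_slots()
        },
        seed=seed,
        amplitude=amplitude,
        order=order,
    )
    markers = inject_sta(landmarks, frames, profiles, grid)
    return TwoLinkToy(
        grid=grid,
        topology=topology,
        frames=frames,
        landmarks=landmarks,
        markers=markers,
        profiles=profiles,
        joint_locals={("A", "J"): j_a, ("B", "J"): j_b},
        joint_global=joint_global,
    )


@pytest.fixture
def two_link():
    return make_two_link()


@pytest.fixture
def two_link_clean():
    return make_two_link(amplitude=0.0)
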