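"""Result containers shared by the naive and the periodic assimilation paths."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .fourier import FourierCoeffs2D
from .frames import MarkerTrajectorySet, PoseSeries

__all__ = ["ShapeParams", "AssimilationResult"]


@dataclass
class ShapeParams:
    """Per-link shape parameters identified from the periodic marker distance.

    ``C`` is the (constant) inter-landmark distance; ``xi_x``/``xi_y`` are the
    differences between the two markers' STA Fourier coefficient vectors
    (marker 2 minus marker 1), each of length 2K.  ``diagnostics`` records the
    solver's residual norm, the candidate-solution bookkeeping and the chosen
    transverse sign branch.
    """

    C: float
    xi_x: np.ndarray
    xi_y: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xi_x = np.asarray(self.xi_x, dtype=float)
        self.xi_y = np.asarray(self.xi_y, dtype=float)
        if self.C <= 0:
            raise InputError(f"inter-landmark distance must be positive, got {self.C}")
        if self.xi_x.shape != self.xi_y.shape or self.xi_x.ndim != 1:
            raise InputError("xi_x and xi_y must be 1-D vectors of equal length 2K")
        if self.xi_x.shape[0] % 2:
            raise InputError("coefficient-difference vectors must have even length 2K")

    @property
    def order(self) -> int:
        return self.xi_x.shape[0] // 2

    def as_vector(self) -> np.ndarray:
        """``[C, xi_x, xi_y]`` of length 4K+1 (the shape-solve unknown vector)."""
        return np.concatenate([[self.C], self.xi_x, self.xi_y])

    @classmethod
    def from_vector(cls, vec: np.ndarray, **kw) -> "ShapeParams":
        vec = np.asarray(vec, dtype=float)
        two_k = (vec.shape[0] - 1) // 2
        return cls(float(vec[0]), vec[1 : 1 + two_k], vec[1 + two_k :], **kw)

    def flipped_y(self) -> "ShapeParams":
        """The gauge copy with the transverse coefficient sign reversed."""
        return ShapeParams(self.C, self.xi_x.copy(), -self.xi_y, dict(self.diagnostics))


@dataclass
class AssimilationResult:
    """Everything an assimilation run produces.

    ``landmark_frames`` are the estimated landmark-coordinate frames (for the
    naive algorithm these are simply the marker frames, which is exactly its
    approximation); ``link_frames`` the reconstructed link-coordinate frames
    (CoM-anchored when the topology carries landmark geometry).  STA fields are
    ``None`` for the naive algorithm, which does not model STA.
    """

    landmark_frames: dict[str, PoseSeries]
    link_frames: dict[str, PoseSeries]
    joint_locals: dict[tuple[str, str], np.ndarray]
    joint_trajectories: dict[str, np.ndarray]
    joint_angles: dict[str, np.ndarray]
    link_lengths: dict[str, np.ndarray]
    sta: dict[tuple[str, int], FourierCoeffs2D] | None = None
    landmark_markers: MarkerTrajectorySet | None = None
    shapes: dict[str, ShapeParams] | None = None
    report: dict = field(default_factory=dict)

    def joint_local(self, link: str, joint: str) -> np.ndarray:
        try:
            return self.joint_locals[(link, joint)]
        except KeyError:
            raise InputError(f"no local joint position for ({link!r}, {joint!r})") from None
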