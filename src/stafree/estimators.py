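"""scikit-learn-style estimators wrapping the assimilation algorithms.

``X`` is the ``(N, 2M)`` marker matrix of one movement cycle — two columns
``[x, y]`` per marker slot, in the topology's slot order (see
:meth:`LinkageTopology.marker_slots`) — or a :class:`MarkerTrajectorySet`.
``PeriodicAssimilator`` is a transformer: ``fit`` identifies the STA and the
joint geometry, ``transform`` returns the STA-free landmark-marker matrix.
Both estimators expose the full assimilation result and compose with sklearn
pipelines and ``clone``/``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InputError
from .fourier import CycleGrid
from .frames import (
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
    marker_frames,
    to_global,
)
from .naive import naive_assimilate
from .periodic import assimilate_periodic, marker_frame_in_landmark

__all__ = ["NaiveAssimilator", "PeriodicAssimilator"]


class _AssimilatorBase(BaseEstimator):
    def _coerce(self, X) -> MarkerTrajectorySet:
        if self.topology is None:
            raise InputError("estimator needs a LinkageTopology (topology=...)")
        if isinstance(X, MarkerTrajectorySet):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError(f"marker matrix must be 2-D, got shape {X.shape}")
        grid = CycleGrid(X.shape[0], duration=self.cycle_duration)
        return MarkerTrajectorySet.from_matrix(X, self.topology, grid)

    def _store_common(self, X, markers: MarkerTrajectorySet) -> None:
        self.n_features_in_ = (
            2 * len(self.topology.marker_slots())
            if isinstance(X, MarkerTrajectorySet)
            else np.asarray(X).shape[1]
        )
        self.grid_ = markers.grid
        self.joint_locals_ = self.result_.joint_locals
        self.joint_trajectories_ = self.result_.joint_trajectories
        self.joint_angles_ = self.result_.joint_angles
        self.link_lengths_ = self.result_.link_lengths


class NaiveAssimilator(_AssimilatorBase):
    """Joint-constraint baseline: constant local joints on raw marker frames.

    Parameters
    ----------
    topology : LinkageTopology
        Links, joints and angle conventions.
    cycle_duration : float, optional
        Cycle duration in seconds (only used when X is a bare matrix).

    Attributes (after ``fit``)
    --------------------------
    result_ : AssimilationResult
    joint_locals_, joint_trajectories_, joint_angles_, link_lengths_
        Convenience views into ``result_``.
    """

    def __init__(self, topology: LinkageTopology | None = None, cycle_duration: float | None = None):
        self.topology = topology
        self.cycle_duration = cycle_duration

    def fit(self, X, y=None):
        markers = self._coerce(X)
        self.result_ = naive_assimilate(markers, self.topology)
        self._store_common(X, markers)
        return self


class PeriodicAssimilator(TransformerMixin, _AssimilatorBase):
    """Periodic-STA identification and removal (the proposed algorithm).

    ``fit`` identifies, per link, the inter-landmark distance and the STA
    Fourier coefficients of both markers, plus every constant local joint
    position; ``transform`` maps a marker matrix of the same cycle to its
    STA-free landmark-marker matrix.

    Parameters
    ----------
    topology : LinkageTopology
    order : int, default 4
        Fourier order K of the STA expansion.
    cycle_duration : float, optional
    shape_tol : float, optional
        Residual tolerance of the shape solve (default ``1e-9 * gamma``).
    accept_rms : float, default 1e-9
        Joint-residual RMS (m) below which the candidate selection is accepted.
    max_sweeps : int, default 3
        Block-coordinate sweeps over spurious-solution candidates.

    Attributes (after ``fit``)
    --------------------------
    result_ : AssimilationResult
    shapes_ : dict of ShapeParams per link
    sta_coeffs_ : dict of FourierCoeffs2D per (link, marker)
    joint_locals_, joint_trajectories_, joint_angles_, link_lengths_
    """

    def __init__(
        self,
        topology: LinkageTopology | None = None,
        order: int = 4,
        cycle_duration: float | None = None,
        shape_tol: float | None = None,
        accept_rms: float = 1e-9,
        max_sweeps: int = 3,
    ):
        self.topology = topology
        self.order = order
        self.cycle_duration = cycle_duration
        self.shape_tol = shape_tol
        self.accept_rms = accept_rms
        self.max_sweeps = max_sweeps

    def fit(self, X, y=None):
        markers = self._coerce(X)
        self.result_ = assimilate_periodic(
            markers,
            self.topology,
            order=self.order,
            shape_tol=self.shape_tol,
            accept_rms=self.accept_rms,
            max_sweeps=self.max_sweeps,
        )
        self.shapes_ = self.result_.shapes
        self.sta_coeffs_ = self.result_.sta
        self._store_common(X, markers)
        return self

    def transform(self, X) -> np.ndarray:
        """STA-free landmark-marker matrix for a marker matrix of the fitted cycle.

        The fitted shape parameters and STA coefficients define, per link, the
        excursion and tilt of the marker frame within the landmark frame; the
        transform rebuilds the marker frames from ``X``, strips that excursion
        and places the landmark markers at ``+-C/2`` on the landmark axis.
        """
        check_is_fitted(self, "result_")
        markers = self._coerce(X)
        frames = marker_frames(markers, self.topology)
        out = {}
        for name in self.topology.links:
            shape = self.shapes_[name]
            q1 = self.sta_coeffs_[(name, 1)]
            offsets, _, rot = marker_frame_in_landmark(shape, q1, markers.grid)
            a_tilde = frames[name].rotations @ np.swapaxes(rot, 1, 2)
            o_tilde = frames[name].origins - np.einsum("nij,nj->ni", a_tilde, offsets)
            series = PoseSeries(o_tilde, a_tilde)
            for j, sign in ((1, -1.0), (2, 1.0)):
                out[(name, j)] = to_global(series, np.array([sign * shape.C / 2.0, 0.0]))
        corrected = MarkerTrajectorySet(out, markers.grid)
        return corrected.as_matrix(self.topology)
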