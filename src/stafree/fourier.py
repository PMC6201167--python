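"""Truncated Fourier machinery for signals sampled over exactly one cycle.

Conventions
-----------
A cycle holds ``N`` uniform samples indexed ``n = 1..N`` at phases ``2*pi*n/N``;
the cycle endpoint is not duplicated (sample ``N+1`` is sample ``1``).  A
coefficient vector of order ``K`` stacks the ``K`` cosine coefficients first and
the ``K`` sine coefficients second, ``[a_1..a_K, b_1..b_K]``.  Soft-tissue
artifact series carry no constant (DC) term: any constant marker offset is by
construction absorbed into the landmark definition, so only the zero-mean part
of an artifact is identifiable.

Fitting is ordinary least squares on the uniform grid (equivalent to DFT
truncation there), so any ``N`` is first-class, not just powers of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "CycleGrid",
    "FourierCoeffs2D",
    "DistanceSqSpectrum",
    "basis_row",
    "basis_matrix",
    "eval_series",
    "eval_coeffs",
    "fit_series",
    "fit_coeffs",
]


@dataclass(frozen=True)
class CycleGrid:
    """Uniform sampling of one movement cycle.

    Parameters
    ----------
    n_samples : int
        Number of samples ``N`` per cycle.
    duration : float, optional
        Cycle duration ``T`` in seconds; required only for time derivatives.
    """

    n_samples: int
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InputError(f"cycle needs at least 2 samples, got {self.n_samples}")
        if self.duration is not None and self.duration <= 0:
            raise InputError(f"cycle duration must be positive, got {self.duration}")

    @property
    def phases(self) -> np.ndarray:
        """Phases ``2*pi*n/N`` for ``n = 1..N``."""
        n = np.arange(1, self.n_samples + 1)
        return 2.0 * np.pi * n / self.n_samples

    @property
    def times(self) -> np.ndarray:
        """Sample times ``n*T/N`` (requires ``duration``)."""
        if self.duration is None:
            raise InputError("grid has no duration; cannot produce times")
        return self.phases * self.duration / (2.0 * np.pi)

    def check_order(self, order: int) -> None:
        """Reject expansion orders that alias on this grid (``K >= N/2``)."""
        if order < 1:
            raise InputError(f"Fourier order must be >= 1, got {order}")
        if 2 * order >= self.n_samples:
            raise InputError(
                f"order K={order} aliases on a grid of N={self.n_samples} samples "
                f"(need K < N/2)"
            )


@dataclass
class FourierCoeffs2D:
    """Order-``K`` sine/cosine coefficients of a zero-mean periodic 2-D signal.

    ``qx`` and ``qy`` each stack ``[a_1..a_K, b_1..b_K]`` (meters).  There is
    deliberately no DC term.
    """

    order: int
    qx: np.ndarray
    qy: np.ndarray

    def __post_init__(self) -> None:
        self.qx = np.asarray(self.qx, dtype=float)
        self.qy = np.asarray(self.qy, dtype=float)
        if self.qx.shape != (2 * self.order,) or self.qy.shape != (2 * self.order,):
            raise InputError(
                f"coefficient vectors must have length 2K={2 * self.order}, "
                f"got {self.qx.shape} and {self.qy.shape}"
            )

    @classmethod
    def zeros(cls, order: int) -> "FourierCoeffs2D":
        return cls(order, np.zeros(2 * order), np.zeros(2 * order))

    def as_stacked(self) -> np.ndarray:
        """Concatenated ``[qx, qy]`` vector of length 4K."""
        return np.concatenate([self.qx, self.qy])


@dataclass
class DistanceSqSpectrum:
    """Fourier spectrum of a squared inter-marker distance series.

    Squaring an order-``K`` band-limited signal doubles the bandwidth, so the
    harmonics run up to ``2K``: ``alpha``/``beta`` have length ``2K`` and
    ``gamma`` is the constant term (all in m^2).
    """

    order: int  # base STA order K; harmonics run to 2K
    gamma: float
    alpha: np.ndarray
    beta: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != (2 * self.order,) or self.beta.shape != (2 * self.order,):
            raise InputError(
                f"distance spectrum needs 2K={2 * self.order} harmonics, "
                f"got {self.alpha.shape} and {self.beta.shape}"
            )

    def as_vector(self) -> np.ndarray:
        """``[gamma, alpha_1..alpha_2K, beta_1..beta_2K]`` of length 4K+1."""
        return np.concatenate([[self.gamma], self.alpha, self.beta])


def basis_row(n: int, grid: CycleGrid, order: int) -> np.ndarray:
    """Row ``P[n] = [cos(2*pi*k*n/N)..., sin(2*pi*k*n/N)...]`` for ``k=1..K``.

    ``n`` is 1-based, ``1 <= n <= N``.
    """
    if not 1 <= n <= grid.n_samples:
        raise InputError(f"sample index n={n} outside 1..{grid.n_samples}")
    grid.check_order(order)
    k = np.arange(1, order + 1)
    phase = 2.0 * np.pi * k * n / grid.n_samples
    return np.concatenate([np.cos(phase), np.sin(phase)])


def basis_matrix(grid: CycleGrid, order: int, with_dc: bool = False) -> np.ndarray:
    """Design matrix stacking ``basis_row(n)`` for ``n = 1..N``.

    With ``with_dc`` a leading column of ones is prepended.  On the uniform
    grid the Gram matrix is diagonal: ``N`` for the DC column and ``N/2`` for
    every harmonic column (exact orthogonality, the discrete analogue of the
    continuous one).
    """
    grid.check_order(order)
    k = np.arange(1, order + 1)
    phase = np.outer(grid.phases, k)  # (N, K)
    mat = np.hstack([np.cos(phase), np.sin(phase)])
    if with_dc:
        mat = np.hstack([np.ones((grid.n_samples, 1)), mat])
    return mat


def fit_coeffs(
    signal: np.ndarray, grid: CycleGrid, order: int, with_dc: bool = False
) -> tuple[float | np.ndarray, np.ndarray]:
    """Least-squares projection of a 1-D (or column-stacked) periodic signal.

    Returns ``(dc, coeffs)`` where ``coeffs`` stacks cosines then sines along
    the first axis.  Without ``with_dc`` the returned ``dc`` is 0 and the mean
    of the signal is simply not represented.  Exact interpolation holds for
    signals band-limited to ``order``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != grid.n_samples:
        raise InputError(
            f"signal length {signal.shape[0]} != grid samples {grid.n_samples}"
        )
    n_cols = 2 * order + (1 if with_dc else 0)
    if grid.n_samples < n_cols:
        raise InputError(
            f"grid of N={grid.n_samples} cannot support a fit with {n_cols} parameters"
        )
    design = basis_matrix(grid, order, with_dc=with_dc)
    sol, *_ = np.linalg.lstsq(design, signal, rcond=None)
    if with_dc:
        return sol[0], sol[1:]
    zero = 0.0 if signal.ndim == 1 else np.zeros(signal.shape[1])
    return zero, sol


def fit_series(signal: np.ndarray, grid: CycleGrid, order: int) -> FourierCoeffs2D:
    """Fit an ``(N, 2)`` periodic signal with a DC-free order-``K`` series."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] != 2:
        raise InputError(f"expected an (N, 2) signal, got shape {signal.shape}")
    _, coef = fit_coeffs(signal, grid, order, with_dc=False)
    return FourierCoeffs2D(order, coef[:, 0], coef[:, 1])


def eval_coeffs(dc: float, coeffs: np.ndarray, grid: CycleGrid) -> np.ndarray:
    """Evaluate ``dc + basis @ coeffs`` on the grid (1-D signal)."""
    order = coeffs.shape[0] // 2
    if coeffs.shape[0] != 2 * order:
        raise InputError("coefficient vector length must be even (cos+sin blocks)")
    return dc + basis_matrix(grid, order) @ coeffs


def eval_series(coeffs: FourierCoeffs2D, grid: CycleGrid) -> np.ndarray:
    """Evaluate a 2-D DC-free series as an ``(N, 2)`` signal."""
    if grid.n_samples < 4 * coeffs.order + 2:
        raise InputError(
            f"grid of N={grid.n_samples} too short for order K={coeffs.order} "
            f"(need N >= 4K+2)"
        )
    design = basis_matrix(grid, coeffs.order)
    return np.column_stack([design @ coeffs.qx, design @ coeffs.qy])
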