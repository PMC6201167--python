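"""Periodic soft-tissue-artifact identification and removal.

The algorithm assumes the STA of every marker is periodic over the movement
cycle and expands it in a truncated Fourier series in the (unknown) landmark
frame of its link.  Identification proceeds in two stages:

1. *Shape stage* (per link).  The squared inter-marker distance is a
   coordinate-free observable; under the STA model it equals
   ``(C + P[n] xi_x)^2 + (P[n] xi_y)^2`` where ``C`` is the inter-landmark
   distance and ``xi`` the difference between the two markers' STA coefficient
   vectors.  Matching its Fourier spectrum (constant plus harmonics up to 2K)
   term-wise against the data yields 4K+1 quadratic equations in the 4K+1
   unknowns ``(C, xi_x, xi_y)``.  Because the transverse part enters only
   quadratically, the system has a discrete set of solutions (root-pair
   selections of a spectral factorization); all of them are enumerated here
   and the final choice is deferred to the joint-constraint cost.

2. *Linear stage* (whole linkage).  With the shape parameters fixed, the tilt
   of each marker frame relative to its landmark frame is known, and the
   joint-constraint residual becomes linear in the remaining unknowns (each
   link's marker-1 STA coefficients and each constant local joint position).
   One global linear least-squares solve over all joints and samples recovers
   them; the joint trajectories, landmark frames, STA-free markers, link
   frames and joint angles follow by direct reconstruction.

The joint-constraint cost is a sum of residual norms in the source
formulation; it is minimized here as a sum of squared norms (exact linear
least squares); both values are reported.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .errors import InputError, ShapeSolveError, SolverError
from .fourier import (
    CycleGrid,
    DistanceSqSpectrum,
    FourierCoeffs2D,
    basis_matrix,
    fit_coeffs,
)
from .frames import (
    LinkageTopology,
    MarkerTrajectorySet,
    PoseSeries,
    compose,
    joint_angles,
    marker_frames,
    rotation_matrix,
    to_global,
)
from .naive import StaInit, link_length_series, naive_assimilate, naive_sta_init
from .results import AssimilationResult, ShapeParams

__all__ = [
    "distance_sq_spectrum",
    "shape_residual",
    "solve_shape",
    "marker_frame_in_landmark",
    "assemble_solve",
    "reconstruct",
    "assimilate_periodic",
]


# ---------------------------------------------------------------------------
# Shape stage


def distance_sq_spectrum(
    m1: np.ndarray, m2: np.ndarray, grid: CycleGrid, order: int
) -> DistanceSqSpectrum:
    """Fourier spectrum (with DC, harmonics to 2K) of the squared marker distance."""
    if grid.n_samples < 8 * order + 2:
        raise InputError(
            f"N={grid.n_samples} too short to resolve harmonics up to 2K={2 * order} "
            f"with margin (need N >= 8K+2)"
        )
    d2 = np.sum((np.asarray(m2, float) - np.asarray(m1, float)) ** 2, axis=1)
    gamma, coef = fit_coeffs(d2, grid, 2 * order, with_dc=True)
    residual = d2 - (gamma + basis_matrix(grid, 2 * order) @ coef)
    return DistanceSqSpectrum(
        order,
        float(gamma),
        coef[: 2 * order],
        coef[2 * order :],
        diagnostics={"fit_residual": float(np.abs(residual).max())},
    )


def _model_distance_sq(params: ShapeParams, grid: CycleGrid) -> np.ndarray:
    design = basis_matrix(grid, params.order)
    u = params.C + design @ params.xi_x
    w = design @ params.xi_y
    return u * u + w * w


def shape_residual(
    params: ShapeParams, spectrum: DistanceSqSpectrum, grid: CycleGrid
) -> np.ndarray:
    """Term-wise coefficient mismatch, model minus data: length 4K+1.

    The model series is evaluated on the grid and Fourier-fitted at order 2K
    with DC — numerically identical to the symbolic product-to-sum expansion
    for these band-limited series — and the stacked coefficient differences
    ``[gamma, alpha_1..2K, beta_1..2K]`` are returned.
    """
    if params.order != spectrum.order:
        raise InputError(
            f"shape order K={params.order} != spectrum order K={spectrum.order}"
        )
    s = _model_distance_sq(params, grid)
    gamma, coef = fit_coeffs(s, grid, 2 * spectrum.order, with_dc=True)
    model = np.concatenate([[gamma], coef])
    return model - spectrum.as_vector()


def _laurent_coefficients(spectrum: DistanceSqSpectrum) -> np.ndarray:
    """Complex coefficients d_m, m = -2K..2K, of the distance-squared series."""
    two_k = 2 * spectrum.order
    d = np.zeros(2 * two_k + 1, dtype=complex)
    d[two_k] = spectrum.gamma
    for k in range(1, two_k + 1):
        d[two_k + k] = 0.5 * (spectrum.alpha[k - 1] - 1j * spectrum.beta[k - 1])
        d[two_k - k] = 0.5 * (spectrum.alpha[k - 1] + 1j * spectrum.beta[k - 1])
    return d


def _candidate_from_z(
    z: np.ndarray, grid: CycleGrid, order: int
) -> ShapeParams | None:
    """Shape parameters from a complex factor ``z = u + i w`` sampled on the grid."""
    c0 = z.mean()
    if abs(c0) < 1e-12 * max(1.0, np.abs(z).max()):
        return None
    z = z * (np.conj(c0) / abs(c0))
    u, w = z.real, z.imag
    if u.min() <= 0.0:
        return None  # markers would cross; geometrically invalid
    c = float(u.mean())
    _, xi_x = fit_coeffs(u - c, grid, order)
    _, xi_y = fit_coeffs(w, grid, order)
    return ShapeParams(c, xi_x, xi_y)


def _factorization_candidates(
    spectrum: DistanceSqSpectrum, grid: CycleGrid
) -> list[ShapeParams]:
    """All solutions of the distance-identity system by spectral factorization.

    The squared distance is a positive trigonometric polynomial, hence equals
    ``|z(phi)|^2`` for a complex trigonometric polynomial ``z`` of half its
    degree (Fejer-Riesz); the distinct factorizations — one root of each
    reciprocal-conjugate root pair of the associated algebraic polynomial —
    enumerate the discrete solution set, including the true parameters and all
    spurious ones, with the transverse sign pairs appearing as conjugate
    factors.
    """
    d = _laurent_coefficients(spectrum)
    scale = np.abs(d).max()
    if scale == 0.0:
        raise ShapeSolveError("squared-distance spectrum is identically zero")
    # trim negligible leading/trailing coefficients (STA order below K)
    sig = np.nonzero(np.abs(d) > 1e-12 * scale)[0]
    two_k = 2 * spectrum.order
    m_max = int(max(abs(sig.min() - two_k), abs(sig.max() - two_k)))
    if m_max == 0:
        return [ShapeParams(float(np.sqrt(spectrum.gamma)),
                            np.zeros(2 * spectrum.order), np.zeros(2 * spectrum.order))]
    m_max += m_max % 2  # the factor degree is m_max/2; keep it integral
    poly = d[two_k - m_max : two_k + m_max + 1][::-1]  # np.roots wants descending powers
    roots = np.roots(poly)
    order_idx = np.argsort(np.abs(roots))
    inside = list(roots[order_idx[:m_max]])
    outside = list(roots[order_idx[m_max:]])
    pairs = []
    for r in inside:
        target = 1.0 / np.conj(r)
        j = int(np.argmin(np.abs(np.array(outside) - target)))
        pairs.append((r, outside.pop(j)))
    phase = np.exp(1j * grid.phases)
    half = m_max // 2
    lead = np.exp(-1j * half * grid.phases)
    # per-pair factors evaluated on the grid
    fac_in = np.stack([phase - r for r, _ in pairs])  # (m_max, N)
    fac_out = np.stack([phase - s for _, s in pairs])
    d2 = _model_value(spectrum, grid)
    candidates = []
    for mask in range(1 << m_max):
        z = lead.copy()
        for j in range(m_max):
            z = z * (fac_out[j] if (mask >> j) & 1 else fac_in[j])
        power = np.mean(np.abs(z) ** 2)
        if power <= 0:
            continue
        z = z * np.sqrt(max(np.mean(d2), 0.0) / power)
        cand = _candidate_from_z(z, grid, spectrum.order)
        if cand is not None:
            candidates.append(cand)
    # dedupe numerically identical candidates
    unique: list[ShapeParams] = []
    for cand in candidates:
        vec = cand.as_vector()
        if not any(np.allclose(vec, u.as_vector(), atol=1e-10) for u in unique):
            unique.append(cand)
    return unique


def _model_value(spectrum: DistanceSqSpectrum, grid: CycleGrid) -> np.ndarray:
    design = basis_matrix(grid, 2 * spectrum.order)
    return spectrum.gamma + design @ np.concatenate([spectrum.alpha, spectrum.beta])


def _tilt_series(params: ShapeParams, grid: CycleGrid) -> np.ndarray:
    design = basis_matrix(grid, params.order)
    return np.arctan2(design @ params.xi_y, params.C + design @ params.xi_x)


def _init_score(cand: ShapeParams, init: StaInit | None, grid: CycleGrid) -> float:
    if init is None:
        return float(np.linalg.norm(cand.xi_y))  # prefer mild tilt absent guidance
    score = abs(cand.C - init.shape.C) + float(
        np.linalg.norm(cand.xi_x - init.shape.xi_x)
    )
    if init.tilt_estimate is not None:
        tilt = _tilt_series(cand, grid)
        tilt = tilt - tilt.mean()
        score += float(np.sqrt(np.mean((tilt - init.tilt_estimate) ** 2)))
    return score


def solve_shape(
    spectrum: DistanceSqSpectrum,
    init: StaInit | ShapeParams | None,
    grid: CycleGrid,
    tol: float | None = None,
) -> ShapeParams:
    """Solve the 4K+1 quadratic distance-identity system for one link.

    All discrete solutions are enumerated by spectral factorization, ranked by
    proximity to the naive initialization, and the preferred one is polished
    by a Newton root solve on :func:`shape_residual`.  The full ranked
    candidate list is kept in the diagnostics so the linear stage can revisit
    the choice by final joint-constraint cost (the transverse sign ambiguity
    ``xi_y -> -xi_y``, which leaves the distance invariant, appears there as a
    conjugate candidate).  The gauge copy ``(-C, -xi_x)`` is excluded by the
    ``C > 0`` convention.
    """
    if isinstance(init, ShapeParams):
        init = StaInit("", FourierCoeffs2D.zeros(init.order),
                       FourierCoeffs2D.zeros(init.order), init)
    tol = tol if tol is not None else 1e-9 * max(spectrum.gamma, 1e-12)
    candidates = _factorization_candidates(spectrum, grid)
    if not candidates:
        raise ShapeSolveError(
            "no geometrically valid factorization of the distance spectrum "
            "(markers crossing or degenerate data)"
        )
    ranked = sorted(candidates, key=lambda c: _init_score(c, init, grid))
    best = _polish_shape(ranked[0], spectrum, grid)
    ranked[0] = best
    res = float(np.linalg.norm(shape_residual(best, spectrum, grid)))
    if res > tol:
        raise ShapeSolveError(
            f"shape solve residual {res:.3e} m^2 exceeds tolerance {tol:.3e}; "
            "the initialization may be outside the basin of the true solution — "
            "consider a different initialization"
        )
    best.diagnostics.update(
        {
            "residual_norm": res,
            "n_candidates": len(ranked),
            "candidates": ranked,
            "init_scores": [_init_score(c, init, grid) for c in ranked],
            "sign_branch": int(np.sign(best.xi_y[np.argmax(np.abs(best.xi_y))] or 1.0)),
        }
    )
    return best


def _polish_shape(
    cand: ShapeParams, spectrum: DistanceSqSpectrum, grid: CycleGrid
) -> ShapeParams:
    """Newton polish of one candidate; enforces the C > 0 gauge."""
    res0 = np.linalg.norm(shape_residual(cand, spectrum, grid))
    if res0 < 1e-13 * max(spectrum.gamma, 1e-12):
        return cand

    def fun(vec):
        return shape_residual(_from_vec(vec), spectrum, grid)

    def _from_vec(vec):
        two_k = 2 * spectrum.order
        c = vec[0]
        xi_x, xi_y = vec[1 : 1 + two_k], vec[1 + two_k :]
        if c <= 0:  # reflect the (-C, -xi_x) gauge copy back to C > 0
            c, xi_x = -c, -xi_x
        return ShapeParams(max(c, 1e-12), xi_x, xi_y)

    sol = optimize.root(fun, cand.as_vector(), method="hybr", tol=1e-13)
    out = _from_vec(sol.x)
    if np.linalg.norm(shape_residual(out, spectrum, grid)) <= res0:
        out.diagnostics["newton_iterations"] = int(sol.nfev)
        return out
    return cand


# ---------------------------------------------------------------------------
# Marker frame relative to landmark frame


def marker_frame_in_landmark(
    params: ShapeParams, q1: FourierCoeffs2D, grid: CycleGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Excursion and tilt of the marker frame within the landmark frame.

    Returns ``(offsets (N,2), tilt (N,), rotations (N,2,2))``.  The tilt uses
    the two-argument arctangent of the transverse and axial marker-difference
    components, so it stays continuous and branch-safe; note it depends only
    on ``(C, xi)`` and is therefore available before ``q1`` is identified.
    """
    if q1.order != params.order:
        raise InputError("q1 order does not match shape order")
    design = basis_matrix(grid, params.order)
    u = params.C + design @ params.xi_x
    if np.any(u <= 0.0):
        raise SolverError(
            "axial marker separation non-positive at some sample (markers "
            "crossing); the shape parameters are geometrically invalid"
        )
    tilt = np.arctan2(design @ params.xi_y, u)
    rotations = rotation_matrix(tilt)
    off_x = design @ (q1.qx + 0.5 * params.xi_x)
    off_y = design @ (q1.qy + 0.5 * params.xi_y)
    offsets = np.column_stack([off_x, off_y])
    return offsets, tilt, rotations


# ---------------------------------------------------------------------------
# Linear stage


class _LinearSystem:
    """Assembler for the joint-constraint least-squares problem.

    Unknowns: per link the marker-1 STA coefficients (4K) and per
    (link, joint) incidence one constant local joint position (2).  Rows: two
    per joint per sample.
    """

    def __init__(
        self,
        markers: MarkerTrajectorySet,
        topology: LinkageTopology,
        grid: CycleGrid,
        order: int,
    ) -> None:
        self.topology = topology
        self.grid = grid
        self.order = order
        self.frames = marker_frames(markers, topology)
        self.design = basis_matrix(grid, order)  # (N, 2K)
        self.links = list(topology.links)
        self.q_index = {name: 4 * order * i for i, name in enumerate(self.links)}
        offset = 4 * order * len(self.links)
        self.j_index = {}
        for joint in topology.joints:
            for name in (joint.proximal, joint.distal):
                self.j_index[(name, joint.name)] = offset
                offset += 2
        self.n_unknowns = offset

    def link_blocks(self, name: str, shape: ShapeParams):
        """Per-sample ``A_tilde`` (N,2,2), ``B`` (N,2,4K) and known term h (N,2)."""
        frame = self.frames[name]
        tilt = _tilt_series(shape, self.grid)
        a_tilde = frame.rotations @ rotation_matrix(-tilt)
        n, two_k = self.grid.n_samples, 2 * self.order
        b = np.zeros((n, 2, 2 * two_k))
        b[:, :, :two_k] = a_tilde[:, :, 0:1] * self.design[:, None, :]
        b[:, :, two_k:] = a_tilde[:, :, 1:2] * self.design[:, None, :]
        xi = np.concatenate([shape.xi_x, shape.xi_y])
        h = frame.origins - 0.5 * np.einsum("nij,j->ni", b, xi)
        return a_tilde, b, h

    def assemble(self, shapes: dict[str, ShapeParams]):
        blocks = {name: self.link_blocks(name, shapes[name]) for name in self.links}
        n = self.grid.n_samples
        rows = 2 * n * len(self.topology.joints)
        mat = np.zeros((rows, self.n_unknowns))
        rhs = np.zeros(rows)
        for j_idx, joint in enumerate(self.topology.joints):
            sl = slice(2 * n * j_idx, 2 * n * (j_idx + 1))
            a_blk, b_blk, h_a = blocks[joint.proximal]
            a_blk_b, b_blk_b, h_b = blocks[joint.distal]
            qa, qb = self.q_index[joint.proximal], self.q_index[joint.distal]
            ja = self.j_index[(joint.proximal, joint.name)]
            jb = self.j_index[(joint.distal, joint.name)]
            width = 4 * self.order
            mat[sl, qa : qa + width] = -b_blk.reshape(2 * n, width)
            mat[sl, qb : qb + width] += b_blk_b.reshape(2 * n, width)
            mat[sl, ja : ja + 2] = a_blk.reshape(2 * n, 2)
            mat[sl, jb : jb + 2] = -a_blk_b.reshape(2 * n, 2)
            rhs[sl] = (h_b - h_a).reshape(2 * n)
        return mat, rhs

    def solve(self, shapes: dict[str, ShapeParams]):
        mat, rhs = self.assemble(shapes)
        sol, _, rank, sv = np.linalg.lstsq(mat, rhs, rcond=None)
        res = mat @ sol - rhs
        res2 = res.reshape(-1, 2)
        cost_sq = float(np.sum(res**2))
        cost_sum = float(np.linalg.norm(res2, axis=1).sum())
        null_dim = int(np.sum(sv < 1e-10 * sv[0])) + (self.n_unknowns - len(sv))
        report = {
            "rank": int(rank),
            "condition": float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf,
            "nullspace_dim": null_dim,
            "cost_squared": cost_sq,
            "cost_sum_norm": cost_sum,
            "rms_residual": float(np.sqrt(cost_sq / res2.shape[0])),
        }
        return sol, report

    def scan_link(
        self,
        name: str,
        candidates: list[ShapeParams],
        shapes: dict[str, ShapeParams],
        limit: int | None = None,
    ) -> tuple[int, float]:
        """Best candidate for one link by full-system cost, others held fixed.

        Re-solves the complete linear problem for each trial candidate (all
        coefficients free), which is necessary because neighbouring links'
        coefficients partially compensate a wrong candidate — restricted
        sub-solves misrank.  ``limit`` scans only the first candidates of the
        (initialization-ranked) list.
        """
        best_idx, best_cost = -1, np.inf
        trial = dict(shapes)
        for idx, cand in enumerate(candidates[: limit or len(candidates)]):
            trial[name] = cand
            _, rep = self.solve(trial)
            if rep["cost_squared"] < best_cost:
                best_idx, best_cost = idx, rep["cost_squared"]
        return best_idx, best_cost

    def joint_pair_subcost(self, joint, blocks_a, blocks_b) -> float:
        """Squared cost of one joint's own subproblem (both links' unknowns free).

        For the *true* candidate pair the subproblem residual is exactly zero
        (the truth zeroes every row); a wrong pair generically cannot be
        absorbed by the 4K+2 free parameters per side, so per-joint subcosts
        identify the correct pair without reference to the rest of the chain.
        """
        n = self.grid.n_samples
        width = 4 * self.order
        a_a, b_a, h_a = blocks_a
        a_b, b_b, h_b = blocks_b
        mat = np.concatenate(
            [
                -b_a.reshape(2 * n, width),
                a_a.reshape(2 * n, 2),
                b_b.reshape(2 * n, width),
                -a_b.reshape(2 * n, 2),
            ],
            axis=1,
        )
        rhs = (h_b - h_a).reshape(2 * n)
        sol, *_ = np.linalg.lstsq(mat, rhs, rcond=None)
        return float(np.sum((mat @ sol - rhs) ** 2))

    def select_by_joint_pairs(
        self,
        shapes: dict[str, ShapeParams],
        limit: int = 32,
        tol: float | None = None,
    ) -> tuple[dict[str, ShapeParams], dict]:
        """Per-joint candidate-pair selection over the ranked candidate lists.

        Scans candidate pairs of each joint's two links (initialization-ranked
        order, early exit at a numerically-zero subcost) and assigns each link
        the candidate from its lowest-subcost incident joint.
        """
        n = self.grid.n_samples
        tol = tol if tol is not None else (1e-8**2) * 2 * n
        cand_lists = {
            name: shapes[name].diagnostics.get("candidates") or [shapes[name]]
            for name in self.links
        }
        cache: dict[tuple[str, int], tuple] = {}

        def blocks(name: str, idx: int):
            key = (name, idx)
            if key not in cache:
                cache[key] = self.link_blocks(name, cand_lists[name][idx])
            return cache[key]

        choice: dict[str, tuple[int, float]] = {}
        per_joint: dict[str, tuple[int, int, float]] = {}
        for joint in self.topology.joints:
            a, b = joint.proximal, joint.distal
            la = min(limit, len(cand_lists[a]))
            lb = min(limit, len(cand_lists[b]))
            best = (0, 0, np.inf)
            for ia in range(la):
                for ib in range(lb):
                    cost = self.joint_pair_subcost(joint, blocks(a, ia), blocks(b, ib))
                    if cost < best[2]:
                        best = (ia, ib, cost)
                    if cost < tol:
                        break
                if best[2] < tol:
                    break
            per_joint[joint.name] = best
            for name, idx in ((a, best[0]), (b, best[1])):
                prev = choice.get(name)
                if prev is None or best[2] < prev[1]:
                    choice[name] = (idx, best[2])
        selected = {}
        for name in self.links:
            idx = choice.get(name, (0, np.inf))[0]
            chosen = cand_lists[name][idx]
            chosen.diagnostics.setdefault("candidates", cand_lists[name])
            selected[name] = chosen
        return selected, {"per_joint": per_joint}

    def scan_joint_pair(
        self,
        joint,
        shapes: dict[str, ShapeParams],
        limit: int = 24,
    ) -> tuple[int, int, float]:
        """Joint scan over candidate *pairs* of the two links sharing a joint.

        Escapes coupled discrete minima that single-link moves cannot (a wrong
        pair on both sides of a joint can beat changing either link alone).
        """
        a, b = joint.proximal, joint.distal
        cands_a = (shapes[a].diagnostics.get("candidates") or [shapes[a]])[:limit]
        cands_b = (shapes[b].diagnostics.get("candidates") or [shapes[b]])[:limit]
        best = (-1, -1, np.inf)
        trial = dict(shapes)
        for ia, ca in enumerate(cands_a):
            trial[a] = ca
            for ib, cb in enumerate(cands_b):
                trial[b] = cb
                _, rep = self.solve(trial)
                if rep["cost_squared"] < best[2]:
                    best = (ia, ib, rep["cost_squared"])
        return best


def assemble_solve(
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    shapes: dict[str, ShapeParams],
    grid: CycleGrid | None = None,
    accept_rms: float = 1e-9,
    max_sweeps: int = 3,
) -> tuple[dict[str, FourierCoeffs2D], dict[tuple[str, str], np.ndarray], dict, dict[str, ShapeParams]]:
    """Global linear solve for the STA coefficients and local joint positions.

    Returns ``(q1s, joint_locals, report, shapes)`` where ``shapes`` is the
    final per-link selection.  When a link's diagnostics carry alternative
    shape candidates (spurious factorizations, including the transverse sign
    branches), an exact block-coordinate descent over those candidates is run
    whenever the initial solution's RMS joint residual exceeds ``accept_rms``
    (meters), keeping the selection with the smallest final cost.  Rank
    deficiency beyond machine tolerance is surfaced in the report, never
    hidden.
    """
    grid = grid or markers.grid
    order = next(iter(shapes.values())).order
    system = _LinearSystem(markers, topology, grid, order)
    shapes = dict(shapes)
    sol, report = system.solve(shapes)
    sweeps = 0
    switches = []
    if report["rms_residual"] > accept_rms and max_sweeps > 0:
        # primary selector: per-joint candidate-pair subproblems
        selected, pair_report = system.select_by_joint_pairs(shapes)
        trial_sol, trial_report = system.solve(selected)
        report["joint_pair_selection"] = {
            name: float(best[2]) for name, best in pair_report["per_joint"].items()
        }
        if trial_report["cost_squared"] < report["cost_squared"]:
            for name in system.links:
                if not np.allclose(
                    selected[name].as_vector(), shapes[name].as_vector(), atol=1e-12
                ):
                    switches.append((name, "joint-pair"))
            pair_sel = report["joint_pair_selection"]
            shapes, sol = selected, trial_sol
            report = trial_report
            report["joint_pair_selection"] = pair_sel
    first_sweep_limit = 24  # initialization-ranked head; later sweeps scan all
    while report["rms_residual"] > accept_rms and sweeps < max_sweeps:
        sweeps += 1
        changed = False
        for name in system.links:
            cands = shapes[name].diagnostics.get("candidates")
            if not cands or len(cands) < 2:
                continue
            limit = first_sweep_limit if sweeps == 1 else None
            current_vec = shapes[name].as_vector()
            idx, cost = system.scan_link(name, cands, shapes, limit=limit)
            if cost < report["cost_squared"] and not np.allclose(
                cands[idx].as_vector(), current_vec, atol=1e-12
            ):
                chosen = cands[idx]
                chosen.diagnostics.setdefault("candidates", cands)
                shapes[name] = chosen
                switches.append((name, idx))
                changed = True
                sol, report = system.solve(shapes)
            if report["rms_residual"] <= accept_rms:
                break
        if not changed and report["rms_residual"] > accept_rms:
            # single-link moves exhausted: try candidate pairs across each joint
            for joint in topology.joints:
                ia, ib, cost = system.scan_joint_pair(joint, shapes)
                if cost < report["cost_squared"] * (1.0 - 1e-12):
                    for name, idx in ((joint.proximal, ia), (joint.distal, ib)):
                        cands = shapes[name].diagnostics.get("candidates") or [shapes[name]]
                        chosen = cands[idx]
                        chosen.diagnostics.setdefault("candidates", cands)
                        shapes[name] = chosen
                        switches.append((name, idx))
                    changed = True
                    sol, report = system.solve(shapes)
                    if report["rms_residual"] <= accept_rms:
                        break
        if not changed:
            break
    report["candidate_sweeps"] = sweeps
    report["candidate_switches"] = switches
    if report["nullspace_dim"] > 0:
        report["warning"] = (
            f"linear system has a null space of dimension {report['nullspace_dim']}; "
            "minimum-norm solution returned"
        )
    q1s = {}
    for name in system.links:
        start = system.q_index[name]
        vec = sol[start : start + 4 * order]
        q1s[name] = FourierCoeffs2D(order, vec[: 2 * order], vec[2 * order :])
    locals_ = {
        key: sol[idx : idx + 2].copy() for key, idx in system.j_index.items()
    }
    return q1s, locals_, report, shapes


# ---------------------------------------------------------------------------
# Reconstruction and orchestration


def reconstruct(
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    shapes: dict[str, ShapeParams],
    q1s: dict[str, FourierCoeffs2D],
    joint_locals: dict[tuple[str, str], np.ndarray],
    grid: CycleGrid | None = None,
    report: dict | None = None,
) -> AssimilationResult:
    """STA-free kinematics from the identified parameters.

    Landmark frames come from the marker frames stripped of the identified
    marker-frame excursion and tilt; landmark markers sit at ``+-C/2`` on the
    landmark x-axis; each joint's global trajectory is the average of the two
    adjacent links' predictions; link frames and joint angles follow from the
    topology's landmark geometry.
    """
    grid = grid or markers.grid
    frames = marker_frames(markers, topology)
    landmark_frames: dict[str, PoseSeries] = {}
    sta: dict[tuple[str, int], FourierCoeffs2D] = {}
    landmark_positions: dict[tuple[str, int], np.ndarray] = {}
    for name in topology.links:
        shape, q1 = shapes[name], q1s[name]
        offsets, _, rotations = marker_frame_in_landmark(shape, q1, grid)
        a_tilde = frames[name].rotations @ np.swapaxes(rotations, 1, 2)
        o_tilde = frames[name].origins - np.einsum("nij,nj->ni", a_tilde, offsets)
        landmark_frames[name] = PoseSeries(o_tilde, a_tilde)
        q2 = FourierCoeffs2D(q1.order, q1.qx + shape.xi_x, q1.qy + shape.xi_y)
        sta[(name, 1)], sta[(name, 2)] = q1, q2
        for j, sign in ((1, -1.0), (2, 1.0)):
            landmark_positions[(name, j)] = to_global(
                landmark_frames[name], np.array([sign * shape.C / 2.0, 0.0])
            )
    trajectories: dict[str, np.ndarray] = {}
    per_link_joint: dict[tuple[str, str], np.ndarray] = {}
    for joint in topology.joints:
        pa = to_global(landmark_frames[joint.proximal], joint_locals[(joint.proximal, joint.name)])
        pb = to_global(landmark_frames[joint.distal], joint_locals[(joint.distal, joint.name)])
        per_link_joint[(joint.proximal, joint.name)] = pa
        per_link_joint[(joint.distal, joint.name)] = pb
        trajectories[joint.name] = 0.5 * (pa + pb)
    link_frames = {
        name: compose(landmark_frames[name], topology.link_frame_in_landmark(name))
        for name in topology.links
    }
    angles = joint_angles(link_frames, topology)
    lengths = link_length_series(topology, link_frames, trajectories)
    report = dict(report or {})
    report["method"] = "periodic"
    report["joint_agreement_max"] = {
        joint.name: float(
            np.linalg.norm(
                per_link_joint[(joint.proximal, joint.name)]
                - per_link_joint[(joint.distal, joint.name)],
                axis=1,
            ).max()
        )
        for joint in topology.joints
    }
    return AssimilationResult(
        landmark_frames=landmark_frames,
        link_frames=link_frames,
        joint_locals={k: np.asarray(v, float) for k, v in joint_locals.items()},
        joint_trajectories=trajectories,
        joint_angles=angles,
        link_lengths=lengths,
        sta=sta,
        landmark_markers=MarkerTrajectorySet(landmark_positions, grid),
        shapes=shapes,
        report=report,
    )


def assimilate_periodic(
    markers: MarkerTrajectorySet,
    topology: LinkageTopology,
    order: int = 4,
    shape_tol: float | None = None,
    accept_rms: float = 1e-9,
    max_sweeps: int = 3,
) -> AssimilationResult:
    """Full periodic-STA assimilation pipeline.

    Runs the naive baseline for initialization, identifies each link's shape
    parameters from its distance spectrum, solves the global linear
    joint-constraint problem, and reconstructs STA-free kinematics.
    Deterministic given inputs and options.
    """
    markers.check_topology(topology)
    grid = markers.grid
    naive_result = naive_assimilate(markers, topology)
    inits = naive_sta_init(markers, topology, order, result=naive_result)
    shapes: dict[str, ShapeParams] = {}
    spectra: dict[str, DistanceSqSpectrum] = {}
    for name in topology.links:
        try:
            spectra[name] = distance_sq_spectrum(
                markers.get(name, 1), markers.get(name, 2), grid, order
            )
            shapes[name] = solve_shape(spectra[name], inits[name], grid, tol=shape_tol)
        except SolverError as err:
            raise type(err)(f"shape stage failed for link {name!r}: {err}") from err
    try:
        q1s, locals_, lin_report, shapes = assemble_solve(
            markers, topology, shapes, grid, accept_rms=accept_rms, max_sweeps=max_sweeps
        )
        if lin_report.get("candidate_switches"):
            # candidates picked up during the descent are only root-accurate;
            # polish them against their spectra and re-solve once
            for name in topology.links:
                polished = _polish_shape(shapes[name], spectra[name], grid)
                polished.diagnostics.update(shapes[name].diagnostics)
                polished.diagnostics["residual_norm"] = float(
                    np.linalg.norm(shape_residual(polished, spectra[name], grid))
                )
                shapes[name] = polished
            q1s, locals_, final_report, shapes = assemble_solve(
                markers, topology, shapes, grid, accept_rms=accept_rms, max_sweeps=0
            )
            final_report["candidate_switches"] = lin_report["candidate_switches"]
            final_report["candidate_sweeps"] = lin_report["candidate_sweeps"]
            lin_report = final_report
    except SolverError as err:
        raise type(err)(f"linear stage failed: {err}") from err
    report = {
        "naive_cost_squared": naive_result.report["cost_squared"],
        "naive_cost_sum_norm": naive_result.report["cost_sum_norm"],
        "linear": lin_report,
        "shape_residuals": {
            name: shapes[name].diagnostics.get("residual_norm") for name in shapes
        },
        "order": order,
    }
    return reconstruct(markers, topology, shapes, q1s, locals_, grid, report)
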