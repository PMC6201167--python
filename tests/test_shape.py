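"""Distance-spectrum identification: the per-link quadratic shape system."""

import numpy as np
import pytest

from stafree import (
    CycleGrid,
    DistanceSqSpectrum,
    ShapeParams,
    distance_sq_spectrum,
    shape_residual,
    solve_shape,
)
from stafree.naive import naive_sta_init
from stafree.periodic import _factorization_candidates


def _true_shape(toy, link):
    p1, p2 = toy.profiles.profiles[(link, 1)], toy.profiles.profiles[(link, 2)]
    lm = toy.topology.links[link].landmarks_local
    return ShapeParams(
        float(np.linalg.norm(lm[1] - lm[0])), p2.qx - p1.qx, p2.qy - p1.qy
    )


class TestSpectrum:
    def test_constant_distance(self):
        grid = CycleGrid(64)
        m1 = np.zeros((64, 2))
        m2 = np.tile([0.37, 0.0], (64, 1))
        spec = distance_sq_spectrum(m1, m2, grid, 2)
        assert spec.gamma == pytest.approx(0.37**2, abs=1e-14)
        np.testing.assert_allclose(spec.alpha, 0.0, atol=1e-14)
        np.testing.assert_allclose(spec.beta, 0.0, atol=1e-14)

    def test_hand_derived_single_cosine(self):
        """m2 - m1 = (d + eps*cos, 0): gamma = d^2 + eps^2/2, alpha_1 = 2*d*eps,
        alpha_2 = eps^2/2 (product-to-sum by hand), everything else zero."""
        grid = CycleGrid(80)
        d, eps = 0.4, 0.02
        m1 = np.zeros((80, 2))
        m2 = np.column_stack([d + eps * np.cos(grid.phases), np.zeros(80)])
        spec = distance_sq_spectrum(m1, m2, grid, 2)
        assert spec.gamma == pytest.approx(d**2 + eps**2 / 2, abs=1e-14)
        assert spec.alpha[0] == pytest.approx(2 * d * eps, abs=1e-14)
        assert spec.alpha[1] == pytest.approx(eps**2 / 2, abs=1e-14)
        np.testing.assert_allclose(spec.alpha[2:], 0.0, atol=1e-14)
        np.testing.assert_allclose(spec.beta, 0.0, atol=1e-14)

    def test_matches_dft_oracle(self, two_link):
        """Spectrum equals a brute-force DFT of the squared-distance series."""
        toy = two_link
        m1, m2 = toy.markers.get("A", 1), toy.markers.get("A", 2)
        spec = distance_sq_spectrum(m1, m2, toy.grid, 2)
        d2 = np.sum((m2 - m1) ** 2, axis=1)
        n = len(d2)
        fft = np.fft.fft(np.roll(d2, 1))  # samples are indexed n = 1..N
        assert spec.gamma == pytest.approx(fft[0].real / n, abs=1e-12)
        for k in range(1, 5):
            assert spec.alpha[k - 1] == pytest.approx(2 * fft[k].real / n, abs=1e-12)
            assert spec.beta[k - 1] == pytest.approx(-2 * fft[k].imag / n, abs=1e-12)


class TestResidual:
    def test_length_is_4k_plus_1(self):
        grid = CycleGrid(200)
        order = 4
        spec = DistanceSqSpectrum(order, 0.16, np.zeros(8), np.zeros(8))
        params = ShapeParams(0.4, np.zeros(8), np.zeros(8))
        res = shape_residual(params, spec, grid)
        assert res.shape == (17,)  # 4K+1 equations for K=4

    def test_zero_at_injected_truth(self, two_link):
        toy = two_link
        for link in ("A", "B"):
            truth = _true_shape(toy, link)
            spec = distance_sq_spectrum(
                toy.markers.get(link, 1), toy.markers.get(link, 2), toy.grid, 2
            )
            res = shape_residual(truth, spec, toy.grid)
            np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_matches_symbolic_product_to_sum(self):
        """Independent sympy oracle at K=1: expand the model squared distance
        symbolically and extract Fourier coefficients by integration."""
        sympy = pytest.importorskip("sympy")
        t = sympy.symbols("t", real=True)
        c_v, ax, bx, ay, by = 0.35, 0.012, -0.007, 0.009, 0.004
        expr = (c_v + ax * sympy.cos(t) + bx * sympy.sin(t)) ** 2 + (
            ay * sympy.cos(t) + by * sympy.sin(t)
        ) ** 2
        two_pi = 2 * sympy.pi
        gamma_s = float(sympy.integrate(expr, (t, 0, two_pi)) / two_pi)
        alphas = [
            float(sympy.integrate(expr * sympy.cos(k * t), (t, 0, two_pi)) / sympy.pi)
            for k in (1, 2)
        ]
        betas = [
            float(sympy.integrate(expr * sympy.sin(k * t), (t, 0, two_pi)) / sympy.pi)
            for k in (1, 2)
        ]
        grid = CycleGrid(64)
        params = ShapeParams(c_v, [ax, bx], [ay, by])
        zero = DistanceSqSpectrum(1, 0.0, np.zeros(2), np.zeros(2))
        model = shape_residual(params, zero, grid)  # residual vs zero = model coeffs
        np.testing.assert_allclose(
            model, [gamma_s] + alphas + betas, atol=1e-12
        )


class TestSolve:
    def test_recovers_known_parameters(self, two_link):
        toy = two_link
        inits = naive_sta_init(toy.markers, toy.topology, order=2)
        for link in ("A", "B"):
            truth = _true_shape(toy, link)
            spec = distance_sq_spectrum(
                toy.markers.get(link, 1), toy.markers.get(link, 2), toy.grid, 2
            )
            sol = solve_shape(spec, inits[link], toy.grid)
            assert sol.C == pytest.approx(truth.C, abs=1e-8)
            np.testing.assert_allclose(sol.xi_x, truth.xi_x, atol=1e-8)
            # transverse part defined up to a global sign
            err = min(
                np.abs(sol.xi_y - truth.xi_y).max(),
                np.abs(sol.xi_y + truth.xi_y).max(),
            )
            assert err < 1e-8

    def test_zero_sta(self, two_link_clean):
        toy = two_link_clean
        spec = distance_sq_spectrum(
            toy.markers.get("A", 1), toy.markers.get("A", 2), toy.grid, 2
        )
        sol = solve_shape(spec, None, toy.grid)
        assert sol.C == pytest.approx(0.4, abs=1e-12)
        np.testing.assert_allclose(sol.xi_x, 0.0, atol=1e-12)
        np.testing.assert_allclose(sol.xi_y, 0.0, atol=1e-12)

    def test_transverse_sign_gauge(self, two_link):
        """(C, xi_x, xi_y) and (C, xi_x, -xi_y) produce identical spectra."""
        toy = two_link
        truth = _true_shape(toy, "A")
        grid = toy.grid
        zero = DistanceSqSpectrum(2, 0.0, np.zeros(4), np.zeros(4))
        a = shape_residual(truth, zero, grid)
        b = shape_residual(truth.flipped_y(), zero, grid)
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_candidates_contain_truth_and_conjugate(self, two_link):
        toy = two_link
        truth = _true_shape(toy, "A")
        spec = distance_sq_spectrum(
            toy.markers.get("A", 1), toy.markers.get("A", 2), toy.grid, 2
        )
        cands = _factorization_candidates(spec, toy.grid)
        def dist(c, t):
            return abs(c.C - t.C) + np.abs(c.xi_x - t.xi_x).max() + np.abs(c.xi_y - t.xi_y).max()
        assert min(dist(c, truth) for c in cands) < 1e-7
        assert min(dist(c, truth.flipped_y()) for c in cands) < 1e-7
        for c in cands:
            assert c.C > 0  # the (-C, -xi_x) gauge copy is excluded

    def test_bad_init_never_silently_wrong(self, two_link):
        """A far-off initialization still yields an exact root of the shape
        system, with the full candidate set kept for downstream selection."""
        toy = two_link
        spec = distance_sq_spectrum(
            toy.markers.get("A", 1), toy.markers.get("A", 2), toy.grid, 2
        )
        bogus = ShapeParams(3.0, 0.5 * np.ones(4), -0.5 * np.ones(4))
        sol = solve_shape(spec, bogus, toy.grid)
        res = np.linalg.norm(shape_residual(sol, spec, toy.grid))
        assert res < 1e-9 * spec.gamma
        assert sol.diagnostics["n_candidates"] >= 2
        truth = _true_shape(toy, "A")
        best = min(
            abs(c.C - truth.C)
            + np.abs(c.xi_x - truth.xi_x).max()
            + min(np.abs(c.xi_y - truth.xi_y).max(), np.abs(c.xi_y + truth.xi_y).max())
            for c in sol.diagnostics["candidates"]
        )
        assert best < 1e-7
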