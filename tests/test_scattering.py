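"""Debye intensity, analytic oracles and transform-pair closure."""

import numpy as np
import pytest
from scipy.optimize import brentq

import micellometry as m
from micellometry.errors import InputError, NumericalError


class TestDebye:
    def test_two_beads_closed_form(self):
        d = 10.0
        model = m.BeadModel([[0, 0, 0], [0, 0, d]], [1.0, 1.0])
        q = np.array([0.05, 0.1, 0.3])
        curve = m.debye_intensity(model, q)
        expected = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(curve.intensity, expected, rtol=1e-12)

    def test_forward_limit_is_total_weight_squared(self):
        model = m.BeadModel([[0, 0, 0], [0, 0, 10.0]], [1.0, 1.0])
        curve = m.debye_intensity(model, np.array([1e-6]))
        assert curve.intensity[0] == pytest.approx(4.0, rel=1e-9)

    def test_single_bead_constant(self):
        model = m.BeadModel([[1.0, 2.0, 3.0]], [2.0])
        curve = m.debye_intensity(model, np.linspace(0.05, 0.5, 5))
        np.testing.assert_allclose(curve.intensity, 4.0)

    def test_matches_sphere_form_factor(self, sphere_model):
        """Bead-sampled Debye curve ≈ analytic sphere form factor, qR ≤ 6."""
        model, truth = sphere_model
        radius = truth.a
        q = np.linspace(0.02, 6.0 / radius, 12)
        bead = m.debye_intensity(model, q)
        exact = m.sphere_form_factor(radius, q)
        n1 = bead.intensity / bead.intensity[0]
        n2 = exact.intensity / exact.intensity[0]
        # 2% relative; the absolute floor covers bead-sampling Monte-Carlo
        # error (~10⁻³ of I(0) at n = 20000), which dominates at the zeros
        np.testing.assert_allclose(n1, n2, rtol=0.02, atol=3e-3)

    def test_rigid_motion_invariance(self, q_grid):
        model, _ = m.make_ellipsoid(20.0, 12.0, 8.0, 400, seed=31)
        rot = np.linalg.qr(np.random.default_rng(1).normal(size=(3, 3)))[0]
        moved = m.BeadModel(model.positions @ rot.T + [5.0, -3.0, 11.0],
                            model.weights)
        a = m.debye_intensity(model, q_grid).intensity
        b = m.debye_intensity(moved, q_grid).intensity
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_empty_model_rejected(self, q_grid):
        with pytest.raises(InputError):
            m.debye_intensity(None, q_grid)


class TestSphereFormFactor:
    def test_forward_limit(self):
        curve = m.sphere_form_factor(20.0, np.array([1e-8, 0.01]))
        assert curve.intensity[0] == pytest.approx(1.0, abs=1e-10)

    def test_first_zero_at_known_root(self):
        """First zero where tan(x) = x: x ≈ 4.4934 (found by bisection)."""
        root = brentq(lambda x: np.tan(x) - x, np.pi / 2 + 1e-6, np.pi * 1.49)
        assert root == pytest.approx(4.4934, abs=1e-3)
        radius = 20.0
        q = np.linspace(root / radius - 0.01, root / radius + 0.01, 401)
        intensity = m.sphere_form_factor(radius, q).intensity
        q_min = q[np.argmin(intensity)]
        assert q_min * radius == pytest.approx(root, abs=1e-2)

    def test_guinier_regime(self):
        radius = 20.0
        q = np.linspace(0.005, 1.0 / radius, 20)
        intensity = m.sphere_form_factor(radius, q).intensity
        guinier = np.exp(-(q**2) * radius**2 / 5.0)
        np.testing.assert_allclose(intensity, guinier, rtol=0.02)


class TestPrExact:
    def test_two_beads_single_bin(self):
        model = m.BeadModel([[0, 0, 0], [0, 0, 30.0]], [1.0, 1.0])
        pr = m.pr_exact(model, bin_width=1.0)
        occupied = np.nonzero(pr.p)[0]
        assert occupied.size == 1
        assert pr.r[occupied[0]] == pytest.approx(30.5, abs=0.51)
        assert pr.d_max == pytest.approx(30.0)

    def test_sphere_histogram_matches_closed_form(self, sphere_model):
        model, truth = sphere_model
        pr = m.pr_exact(model, bin_width=1.0)
        exact = m.sphere_pr(truth.a, r_grid=pr.r)
        scale = np.max(pr.p) / np.max(exact.p)
        resid = np.abs(pr.p - scale * exact.p) / np.max(pr.p)
        assert np.max(resid) < 0.03

    def test_prolate_dmax_bounded_by_construction(self):
        model, truth = m.make_ellipsoid(37.5, 21.0, 21.0, 4000, seed=33)
        pr = m.pr_exact(model, bin_width=0.5)
        assert pr.d_max <= truth.d_max
        assert pr.d_max > 0.95 * truth.d_max

    def test_single_bead_degenerate(self):
        with pytest.raises(NumericalError):
            m.pr_exact(m.BeadModel([[0, 0, 0]], [1.0]), 1.0)


class TestBackTransform:
    def test_forward_value_is_4pi_integral(self):
        pr = m.sphere_pr(20.0)
        curve = m.back_transform(pr, np.array([1e-7]))
        assert curve.intensity[0] == pytest.approx(
            4 * np.pi * np.trapezoid(pr.p, pr.r), rel=1e-6
        )

    def test_zero_pr_gives_zero_intensity(self):
        pr = m.PairDistribution(np.linspace(0, 40, 50), np.zeros(50), d_max=40.0)
        curve = m.back_transform(pr, np.linspace(0.02, 0.5, 10))
        np.testing.assert_array_equal(curve.intensity, 0.0)

    def test_transform_pair_closure(self, sphere_model, q_grid):
        """back_transform ∘ pr_exact ≈ debye_intensity — the central oracle.

        The continuous p(r) cannot carry the Σw² self term of the discrete
        sum, so the comparison removes it (5e-5 of I(0) here).
        """
        model, _ = sphere_model
        q = q_grid[q_grid <= 0.3]
        debye = m.debye_intensity(model, q).intensity - float(np.sum(model.weights**2))
        bt = m.back_transform(m.pr_exact(model, 0.25), q).intensity
        # 2% relative, with an absolute floor at the sphere's deep zeros
        np.testing.assert_allclose(bt, debye, rtol=0.02, atol=1e-4 * debye[0])


class TestScaleTo:
    def test_exact_scale_recovery(self, q_grid):
        theo = m.sphere_form_factor(20.0, q_grid, i0=1.0)
        exp = theo.with_intensity(3.7 * theo.intensity)
        scale, chi = m.scale_to(theo, exp)
        assert scale == pytest.approx(3.7, rel=1e-9)
        assert chi == pytest.approx(0.0, abs=1e-9)

    def test_chi_near_unity_for_matched_noise(self, q_grid):
        rng = np.random.default_rng(44)
        theo = m.sphere_form_factor(20.0, q_grid, i0=100.0)
        sigma = 0.05 * theo.intensity + 0.01
        noisy = m.ScatteringCurve(q_grid, theo.intensity + rng.normal(0, sigma),
                                  sigma=sigma)
        chis = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noisy = m.ScatteringCurve(q_grid,
                                      theo.intensity + rng.normal(0, sigma),
                                      sigma=sigma)
            chis.append(m.scale_to(theo, noisy)[1])
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)

    def test_zero_theoretical_rejected(self, q_grid):
        theo = m.ScatteringCurve(q_grid, np.zeros_like(q_grid))
        exp = m.sphere_form_factor(20.0, q_grid)
        with pytest.raises(NumericalError):
            m.scale_to(theo, exp)

    def test_disjoint_ranges_rejected(self):
        a = m.ScatteringCurve([0.02, 0.03], [1.0, 1.0])
        b = m.ScatteringCurve([0.5, 0.6], [1.0, 1.0])
        with pytest.raises(InputError):
            m.scale_to(a, b)
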