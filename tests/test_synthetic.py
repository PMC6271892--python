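"""Generator ground truth, determinism and construction invariants."""

import numpy as np
import pytest

import micellometry as m
from micellometry.errors import GeometryError, InputError


class TestEllipsoid:
    def test_sphere_ground_truth_rg(self):
        _, truth = m.make_ellipsoid(10.0, 10.0, 10.0, 1000, seed=0)
        assert truth.rg == pytest.approx(np.sqrt(3.0 / 5.0) * 10.0, abs=1e-9)
        assert truth.d_max == 20.0

    def test_micelle_sized_prolate_ground_truth(self):
        _, truth = m.make_ellipsoid(37.5, 21.0, 21.0, 100, seed=0)
        assert truth.d_max == 75.0
        assert truth.axial_ratio == pytest.approx(1.786, abs=0.01)

    def test_empirical_rg_converges_to_closed_form(self, prolate_model):
        model, truth = prolate_model
        centred = model.positions - model.positions.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum(centred**2, axis=1)))
        assert rg == pytest.approx(truth.rg, rel=0.02)

    def test_beads_inside_ellipsoid(self):
        model, _ = m.make_ellipsoid(30.0, 20.0, 10.0, 2000, seed=1)
        scaled = model.positions / np.array([30.0, 20.0, 10.0])
        assert np.all(np.sum(scaled**2, axis=1) <= 1.0 + 1e-12)

    def test_determinism(self):
        a, _ = m.make_ellipsoid(30.0, 20.0, 10.0, 500, seed=7)
        b, _ = m.make_ellipsoid(30.0, 20.0, 10.0, 500, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_too_few_beads_rejected(self):
        with pytest.raises(InputError):
            m.make_ellipsoid(10, 10, 10, 5, seed=0)

    def test_axis_ordering_enforced(self):
        with pytest.raises(GeometryError):
            m.make_ellipsoid(10, 20, 10, 100, seed=0)


class TestCoreShell:
    def test_degenerate_contrast_equals_uniform_sphere(self, q_grid):
        cs = m.make_core_shell_sphere(10.0, 20.0, 1.0, 1.0, 4000, seed=3)
        uni, _ = m.make_ellipsoid(20.0, 20.0, 20.0, 4000, seed=3)
        ics = m.debye_intensity(cs, q_grid).intensity
        iun = m.debye_intensity(uni, q_grid).intensity
        # same seed ⇒ same bead cloud; equal weights ⇒ identical curve
        np.testing.assert_allclose(ics, iun, rtol=1e-12)

    def test_zero_shell_weight_equals_core_only(self, q_grid):
        cs = m.make_core_shell_sphere(10.0, 20.0, 1.0, 0.0, 6000, seed=4)
        inner = cs.positions[np.linalg.norm(cs.positions, axis=1) <= 10.0]
        core = m.BeadModel(inner, np.ones(len(inner)))
        ics = m.debye_intensity(cs, q_grid).intensity
        icore = m.debye_intensity(core, q_grid).intensity
        np.testing.assert_allclose(ics, icore, rtol=1e-12)

    def test_negative_core_contrast_shifts_first_minimum(self):
        """Opposite-sign core–shell contrast pulls the first intensity
        minimum well below the uniform sphere's qR ≈ 4.49, a non-Guinier
        dip the uniform profile cannot produce."""
        from scipy.signal import argrelmin

        q = np.linspace(0.02, 0.35, 70)
        cs = m.make_core_shell_sphere(12.0, 20.0, -1.0, 1.0, 3000, seed=5)
        uni, _ = m.make_ellipsoid(20.0, 20.0, 20.0, 3000, seed=5)
        ics = m.debye_intensity(cs, q).intensity
        iun = m.debye_intensity(uni, q).intensity
        q_min_cs = q[argrelmin(ics)[0][0]]
        q_min_uni = q[argrelmin(iun)[0][0]]
        assert q_min_cs < 0.8 * q_min_uni

    def test_bad_geometry_rejected(self):
        with pytest.raises(GeometryError):
            m.make_core_shell_sphere(20.0, 10.0, 1.0, 1.0, 100, seed=0)


class TestAggregate:
    def test_single_monomer_is_placed_template(self):
        coords = m.make_aggregate(1, seed=9)
        template, labels = m.make_monomer_template()
        assert len(coords) == len(template)
        # rigid placement preserves internal distances
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(
            np.sort(pdist(coords.positions)), np.sort(pdist(template)), atol=1e-8
        )

    def test_tails_buried_relative_to_heads(self):
        coords = m.make_aggregate(12, seed=10)
        centre = coords.positions.mean(axis=0)
        dist = np.linalg.norm(coords.positions - centre, axis=1)
        tails = coords.res_names == "TAI"
        assert dist[tails].mean() < dist[~tails].mean()

    def test_no_clashes(self):
        from scipy.spatial.distance import pdist

        coords = m.make_aggregate(8, seed=11)
        per = len(m.make_monomer_template()[0])
        d = pdist(coords.positions)
        # clash criterion applies between different monomers only
        same = np.zeros(len(coords.positions), dtype=int)
        idx = np.repeat(np.arange(8), per)
        iu, ju = np.triu_indices(len(coords.positions), k=1)
        inter = idx[iu] != idx[ju]
        assert d[inter].min() >= 1.5

    def test_envelope_extents(self):
        """Monomers packed into a 36 × 20 × 20 Å envelope give an
        aggregate whose principal extents track the envelope diameter."""
        coords = m.make_aggregate(20, envelope=(36.0, 20.0, 20.0), seed=12)
        geom = m.principal_extents(coords)
        assert geom.height == pytest.approx(72.0, rel=0.10)
        assert geom.width == pytest.approx(40.0, rel=0.10)


class TestNoisyCurve:
    def test_zero_noise_is_exact_debye(self, small_prolate, q_grid):
        model, _ = small_prolate
        curve = m.make_noisy_curve(model, q_grid, noise_frac=0.0)
        ref = m.debye_intensity(model, q_grid)
        np.testing.assert_array_equal(curve.intensity, ref.intensity)
        assert not curve.smeared

    def test_same_seed_identical(self, small_prolate, q_grid):
        model, _ = small_prolate
        a = m.make_noisy_curve(model, q_grid, noise_frac=0.02, seed=42)
        b = m.make_noisy_curve(model, q_grid, noise_frac=0.02, seed=42)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_noise_magnitude_matches_half_normal_mean(self, small_prolate):
        """E|N(0, f)| = f·sqrt(2/π) ⇒ mean relative deviation ≈ 0.008 at f=1%."""
        model, _ = small_prolate
        q = np.linspace(0.02, 0.6, 200)
        ref = m.debye_intensity(model, q)
        curve = m.make_noisy_curve(model, q, noise_frac=0.01, seed=13)
        mean_dev = np.mean(np.abs(curve.intensity / ref.intensity - 1.0))
        assert mean_dev == pytest.approx(0.01 * np.sqrt(2 / np.pi), rel=0.15)
        np.testing.assert_allclose(curve.sigma, 0.01 * np.abs(ref.intensity))


class TestTitrationGenerator:
    def test_midpoint_at_pka(self):
        curve = m.make_titration(pka=7.0, lambda_acid=340.0, lambda_base=440.0,
                                 ph_grid=[3.0, 5.0, 7.0, 9.0, 11.0], noise_nm=0.0)
        assert curve.wavelength[2] == pytest.approx(390.0)

    def test_acid_limit(self):
        curve = m.make_titration(pka=7.0, lambda_acid=340.0, lambda_base=440.0,
                                 ph_grid=[1.0, 6, 7, 8, 13.0], noise_nm=0.0)
        assert curve.wavelength[0] == pytest.approx(340.0, abs=0.01)
        assert curve.wavelength[-1] == pytest.approx(440.0, abs=0.01)

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(InputError):
            m.make_titration(ph_grid=[-1.0, 7.0, 14.0])


class TestSolvatedBox:
    def test_no_solvent_within_min_dist(self):
        solute = m.make_aggregate(3, seed=20)
        box = m.make_solvated_box(solute, 60.0, 2000, min_dist=2.4, seed=21)
        sol = box.positions[box.res_names == "SOL"]
        slt = box.positions[box.res_names != "SOL"]
        from scipy.spatial import cKDTree

        d, _ = cKDTree(slt).query(sol, k=1)
        assert d.min() >= 2.4

    def test_empty_solute_uniform(self):
        box = m.make_solvated_box(None, 50.0, 5000, seed=22)
        assert len(box) == 5000
        # uniformity: mean position near the box centre
        np.testing.assert_allclose(box.positions.mean(axis=0), [25.0] * 3, atol=1.0)

    def test_ideal_gas_rdf_is_flat(self):
        """g(r) ≈ 1 beyond the excluded shell around a point solute."""
        point = m.CoordinateSet(
            np.array([[25.0, 25.0, 25.0]]), ["X"], ["PT"], [1], ["C"], [12.011],
        )
        box = m.make_solvated_box(point, 50.0, 50000, min_dist=2.0, seed=23)
        ref = box.res_names != "SOL"
        tgt = box.res_names == "SOL"
        prof = m.rdf(box, ref, tgt, r_max=20.0, bin_width=1.0)
        far = prof.r > 4.0
        # one reference atom: ~100–500 expected counts per shell here
        assert np.all(np.abs(prof.g[far] - 1.0) < 0.25)
        assert np.abs(np.mean(prof.g[far]) - 1.0) < 0.03
        near = prof.r < 1.5
        assert np.all(prof.g[near] == 0.0)
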