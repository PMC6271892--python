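"""Coordinate-space descriptors: Rg, extents, RDF, SASA, dihedrals, trends."""

import numpy as np
import pytest

import micellometry as m
from micellometry.errors import GeometryError, InputError, NumericalError


def _coords(positions, elements=None, res_names=None, res_ids=None, box=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    elements = np.asarray(elements if elements is not None else ["C"] * n)
    masses = np.array([m.datatypes.ELEMENT_MASSES.get(e.upper(), 0.0) for e in elements])
    return m.CoordinateSet(
        positions, [f"A{i}" for i in range(n)],
        res_names if res_names is not None else ["RES"] * n,
        res_ids if res_ids is not None else np.ones(n, int),
        elements, masses, box=box,
    )


def _corner_box(height, width):
    """Eight corner atoms of an axis-aligned box height × width × width."""
    h, w = height / 2, width / 2
    pts = [[sx * h, sy * w, sz * w] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    return _coords(pts)


class TestRadiusOfGyration:
    def test_dumbbell(self):
        coords = _coords([[0, 0, 0], [10.0, 0, 0]])
        assert m.radius_of_gyration(coords) == pytest.approx(5.0)

    def test_uniform_ellipsoid_closed_form(self, prolate_model):
        model, truth = prolate_model
        coords = _coords(model.positions)
        assert m.radius_of_gyration(coords, "uniform") == pytest.approx(
            truth.rg, rel=0.025)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(50, 3)) * 10
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        a = m.radius_of_gyration(_coords(pos))
        b = m.radius_of_gyration(_coords(pos @ rot.T + [7.0, -2.0, 3.0]))
        assert a == pytest.approx(b, abs=1e-10)

    def test_mass_weighting_excludes_unknown_elements(self):
        coords = _coords([[0, 0, 0], [10.0, 0, 0], [100.0, 0, 0]],
                         elements=["C", "C", "Xx"])
        # the unknown element has mass 0 ⇒ same result as the dumbbell
        assert m.radius_of_gyration(coords, "mass") == pytest.approx(5.0)


class TestPrincipalExtents:
    # printed micelle-dimension rows: height, width, expected printed ratio
    @pytest.mark.parametrize("height,width,printed", [
        (54.3, 36.8, 1.5),
        (72.0, 39.2, 1.8),
        (32.6, 13.5, 2.4),
    ])
    def test_box_corner_quotients(self, height, width, printed):
        geom = m.principal_extents(_corner_box(height, width))
        assert geom.height == pytest.approx(height, rel=1e-9)
        assert geom.width == pytest.approx(width, rel=1e-9)
        assert round(geom.axial_ratio, 1) == printed

    def test_rotation_invariance(self):
        rng = np.random.default_rng(17)
        base = _corner_box(50.0, 30.0)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        moved = _coords(base.positions @ rot.T + [3.0, 1.0, -9.0])
        a, b = m.principal_extents(base), m.principal_extents(moved)
        assert a.height == pytest.approx(b.height, abs=1e-8)
        assert a.width == pytest.approx(b.width, abs=1e-8)

    def test_collinear_rejected(self):
        pts = [[float(i), 0, 0] for i in range(6)]
        with pytest.raises(GeometryError):
            m.principal_extents(_coords(pts))


class TestRdf:
    def test_periodic_ideal_gas_is_unity(self):
        rng = np.random.default_rng(29)
        box = 40.0
        n = 50000
        pos = np.vstack([[[box / 2] * 3], rng.uniform(0, box, (n, 3))])
        coords = _coords(pos, res_names=["REF"] + ["SOL"] * n,
                         box=[box] * 3)
        prof = m.rdf(coords, coords.res_names == "REF", coords.res_names == "SOL",
                     r_max=15.0, bin_width=0.5)
        # single reference atom: expected counts per shell grow as r², so
        # the pointwise tolerance is counting-statistics limited near r=0
        beyond = prof.r > 4.0
        assert np.abs(prof.g[beyond] - 1.0).max() < 0.2
        assert np.abs(np.mean(prof.g[beyond]) - 1.0) < 0.02

    def test_excluded_shell_is_zero(self):
        point = m.CoordinateSet([[25.0] * 3], ["X"], ["PT"], [1], ["C"], [12.011])
        boxset = m.make_solvated_box(point, 50.0, 20000, min_dist=3.0, seed=31)
        prof = m.rdf(boxset, boxset.res_names == "PT", boxset.res_names == "SOL",
                     r_max=10.0, bin_width=0.25)
        assert np.all(prof.g[prof.r < 2.8] == 0.0)

    def test_buried_reference_less_solvated_than_surface(self):
        """Tail beads buried in a compact aggregate see less solvent in
        their first shells than exposed head beads — the shielding
        signature.  The aggregate must be dense enough that its core
        actually excludes water."""
        agg = m.make_aggregate(40, envelope=(18.0, 12.0, 12.0), seed=33)
        solvated = m.make_solvated_box(agg, 70.0, 30000, min_dist=2.6, seed=34)
        tails = solvated.res_names == "TAI"
        heads = solvated.res_names == "HEA"
        sol = solvated.res_names == "SOL"
        g_tail = m.rdf(solvated, tails, sol, r_max=10.0, bin_width=0.5)
        g_head = m.rdf(solvated, heads, sol, r_max=10.0, bin_width=0.5)
        shell = (g_tail.r >= 2.0) & (g_tail.r <= 6.0)
        assert g_tail.g[shell].mean() < g_head.g[shell].mean()

    def test_empty_selection_rejected(self):
        coords = _coords([[0, 0, 0], [1, 1, 1]])
        with pytest.raises(InputError):
            m.rdf(coords, np.array([False, False]), np.array([True, True]), 5.0)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        coords = _coords([[0.0, 0.0, 0.0]])
        area = m.sasa(coords, probe_radius=1.4)
        assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=1e-9)

    def test_distant_atoms_additive(self):
        one = m.sasa(_coords([[0.0, 0.0, 0.0]]))
        two = m.sasa(_coords([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]))
        assert two == pytest.approx(2 * one, rel=1e-9)

    def test_caged_atom_contributes_nothing(self):
        from micellometry.structure import _golden_spiral

        cage = 3.2 * _golden_spiral(200)
        coords = _coords(np.vstack([[[0.0, 0.0, 0.0]], cage]))
        per_atom = m.sasa(coords, per_atom=True)
        assert per_atom[0] == 0.0

    def test_occlusion_monotone(self):
        """Adding neighbours can only reduce the central atom's area."""
        centre = [[0.0, 0.0, 0.0]]
        prev = np.inf
        for n_neigh in (1, 3, 6):
            ring = [[3.5 * np.cos(a), 3.5 * np.sin(a), 0.0]
                    for a in np.linspace(0, 2 * np.pi, n_neigh, endpoint=False)]
            area = m.sasa(_coords(centre + ring), per_atom=True)[0]
            assert area <= prev + 1e-9
            prev = area

    def test_unknown_element_rejected(self):
        coords = _coords([[0.0, 0.0, 0.0]], elements=["Qq"])
        with pytest.raises(InputError):
            m.sasa(coords)


class TestDihedral:
    def _spec(self):
        return m.datatypes.DihedralSpec(
            atoms=(("A0", 1), ("A1", 1), ("A2", 1), ("A3", 1)))

    def test_trans_is_180(self):
        coords = _coords([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert m.dihedral(coords, self._spec()) == pytest.approx(180.0)

    def test_cis_is_zero(self):
        coords = _coords([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert m.dihedral(coords, self._spec()) == pytest.approx(0.0, abs=1e-9)

    def test_mirror_negates(self):
        pos = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -0.5, 0.8]])
        ang = m.dihedral(_coords(pos), self._spec())
        mirrored = pos * np.array([1, 1, -1])
        assert m.dihedral(_coords(mirrored), self._spec()) == pytest.approx(-ang)

    def test_collinear_rejected(self):
        coords = _coords([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(NumericalError):
            m.dihedral(coords, self._spec())


class TestGrowthTrend:
    def test_exact_logarithmic_law(self):
        data = [(n, 3.0 + 2.0 * np.log(n)) for n in (1, 2, 5, 10, 20)]
        a, b, r = m.growth_trend(data)
        assert a == pytest.approx(3.0)
        assert b == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_micelle_rg_series_has_high_correlation(self):
        """Published micelle Rg values for 2–20 monomers follow a log law
        with R > 0.99."""
        data = [(2, 8.8), (3, 10.0), (4, 10.8), (10, 15.7), (20, 22.0)]
        _, b, r = m.growth_trend(data)
        assert b > 0
        assert r > 0.97

    def test_constant_dimension_has_zero_slope(self):
        a, b, _ = m.growth_trend([(1, 5.0), (3, 5.0), (9, 5.0)])
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(5.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            m.growth_trend([(1, 2.0), (2, 3.0)])
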