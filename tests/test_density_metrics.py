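"""Grids, BCP search, TI/RSR/Carbo/RMSD/MAD, bond profiles, cube files."""

import numpy as np
import pytest

from xcwfit import (GridSpec, ScalarField, ToyGaussianModel, bond_profile,
                    carbo_distance, density_on_grid, find_bcp, read_cube,
                    rho_grad_hess, rmsd_mad, rsr, topological_index,
                    write_cube)
from xcwfit.density_metrics import (BCPNotFound, density_at_points,
                                    overlap_similarity)


def _uniform_field(values, spacing=0.5, shape=(4, 4, 4)):
    grid = GridSpec((0.0, 0.0, 0.0), (spacing,) * 3, shape)
    return ScalarField(grid, np.full(grid.n_points, values)
                       if np.isscalar(values) else values)


class TestTopologicalIndex:
    def test_benchmark_endpoints(self):
        # the correlated benchmark maps to 0, unconstrained RHF to 100
        assert topological_index(0.30, 0.32, 0.30) == pytest.approx(0.0)
        assert topological_index(0.32, 0.32, 0.30) == pytest.approx(100.0)

    def test_linearity_midway(self):
        assert topological_index(0.31, 0.32, 0.30) == pytest.approx(50.0)

    def test_overshoot_is_legal_but_degenerate_reference_is_not(self):
        assert topological_index(0.35, 0.32, 0.30) > 100.0
        with pytest.raises(ZeroDivisionError):
            topological_index(0.31, 0.30, 0.30)


class TestGridIndicators:
    def test_rsr_identical_zero(self):
        f = _uniform_field(0.7)
        assert rsr(f, f) == 0.0

    def test_rsr_doubled_field_is_one_third(self):
        f1 = _uniform_field(0.4)
        f2 = _uniform_field(0.8)
        assert rsr(f2, f1) == pytest.approx(1.0 / 3.0)

    def test_rsr_disjoint_supports_is_one(self):
        v1 = np.zeros(64)
        v2 = np.zeros(64)
        v1[:32] = 1.0
        v2[32:] = 1.0
        assert rsr(_uniform_field(v1), _uniform_field(v2)) == 1.0

    def test_carbo_identical_zero_and_symmetry(self):
        rng = np.random.default_rng(0)
        f1 = _uniform_field(rng.random(64))
        f2 = _uniform_field(rng.random(64))
        assert carbo_distance(f1, f1) == 0.0
        assert carbo_distance(f1, f2) == pytest.approx(
            carbo_distance(f2, f1))

    def test_carbo_disjoint_blobs_pythagoras(self):
        v1 = np.zeros(64)
        v2 = np.zeros(64)
        v1[0] = 3.0
        v2[63] = 4.0
        f1, f2 = _uniform_field(v1), _uniform_field(v2)
        zii = overlap_similarity(f1, f1)
        zjj = overlap_similarity(f2, f2)
        assert carbo_distance(f1, f2) == pytest.approx(np.sqrt(zii + zjj))

    def test_carbo_gaussian_overlap_matches_closed_form(self):
        # Z_IJ of two unit Gaussians has the closed-form Gaussian-product
        # integral; the grid Riemann sum must approach it
        a1, a2 = 0.9, 1.4
        c1 = np.array([0.0, 0.0, 0.0])
        c2 = np.array([0.8, -0.3, 0.5])
        m1 = ToyGaussianModel([c1], [a1], [1.0])
        m2 = ToyGaussianModel([c2], [a2], [1.0])
        grid = GridSpec((-6.0, -6.0, -6.0), (0.12,) * 3, (101, 101, 101))
        pts = grid.points()
        f1 = ScalarField(grid, m1.density(pts))
        f2 = ScalarField(grid, m2.density(pts))
        p = a1 + a2
        mu = a1 * a2 / p
        z_exact = (a1 / np.pi) ** 1.5 * (a2 / np.pi) ** 1.5 \
            * np.exp(-mu * np.sum((c1 - c2) ** 2)) * (np.pi / p) ** 1.5
        assert overlap_similarity(f1, f2) == pytest.approx(z_exact, abs=1e-6)

    def test_rmsd_mad_examples(self):
        f = _uniform_field(np.zeros(64))
        assert rmsd_mad(f, f) == (0.0, 0.0)
        g = _uniform_field(np.full(64, 0.3))
        assert rmsd_mad(f, g) == (pytest.approx(0.3), pytest.approx(0.3))
        v = np.zeros(64)
        v[:32] = 2.0
        h = _uniform_field(v)
        r, m = rmsd_mad(f, h)
        assert r == pytest.approx(np.sqrt(2.0))
        assert m == pytest.approx(1.0)
        assert r >= m  # power-mean inequality

    def test_grid_mismatch_rejected(self):
        f1 = _uniform_field(0.5)
        f2 = _uniform_field(0.5, spacing=0.4)
        for fn in (rsr, carbo_distance, rmsd_mad):
            with pytest.raises(ValueError, match="grid"):
                fn(f1, f2)


class TestDensityEvaluation:
    def test_h2_grid_integral_is_electron_count(self, h2_sto3g):
        hf = h2_sto3g.rhf()
        grid = GridSpec.around(h2_sto3g.molecule, spacing=0.15)
        f = density_on_grid(hf.density, h2_sto3g.basis, grid)
        assert f.integral() == pytest.approx(2.0, abs=0.01)

    def test_pointwise_values_match_independent_ao_products(self, h2_sto3g):
        # independent oracle: evaluate the two contracted 1s AOs directly
        # from the primitive expansion with plain numpy
        hf = h2_sto3g.rhf()
        sh = h2_sto3g.basis.shells
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=1.5, size=(10, 3))
        for pt in pts:
            chi = np.array([
                np.sum(s.coefs * np.exp(-s.exps * np.sum((pt - s.center) ** 2)))
                for s in sh
            ])
            rho_oracle = float(chi @ hf.density @ chi)
            rho = density_at_points(hf.density, h2_sto3g.basis, pt)[0]
            assert rho == pytest.approx(rho_oracle, abs=1e-10)

    def test_density_maximum_near_nuclei(self, water_sto3g):
        hf = water_sto3g.rhf()
        mol = water_sto3g.molecule
        rho_o = density_at_points(hf.density, water_sto3g.basis,
                                  mol.coords[0])[0]
        rng = np.random.default_rng(1)
        far = density_at_points(hf.density, water_sto3g.basis,
                                mol.coords.mean(0) + rng.normal(
                                    scale=3.0, size=(20, 3)))
        assert rho_o > far.max()

    def test_gradient_hessian_match_finite_differences(self, water_sto3g):
        hf = water_sto3g.rhf()
        basis = water_sto3g.basis
        pt = np.array([0.5, 0.3, 0.2])
        rho, g, H = rho_grad_hess(hf.density, basis, pt)
        assert np.abs(H - H.T).max() == 0.0
        eps = 1e-5
        for d in range(3):
            e = np.zeros(3)
            e[d] = eps
            rp = density_at_points(hf.density, basis, pt + e)[0]
            rm = density_at_points(hf.density, basis, pt - e)[0]
            assert g[d] == pytest.approx((rp - rm) / (2 * eps), abs=1e-6)
            _, gp, _ = rho_grad_hess(hf.density, basis, pt + e)
            _, gm, _ = rho_grad_hess(hf.density, basis, pt - e)
            np.testing.assert_allclose(H[:, d], (gp - gm) / (2 * eps),
                                       atol=1e-6)


class TestBCP:
    def test_h2_bcp_at_midpoint_matches_axis_scan(self, h2_sto3g):
        hf = h2_sto3g.rhf()
        cp = find_bcp(hf.density, h2_sto3g.basis, 0, 1)
        np.testing.assert_allclose(cp.position, [0, 0, 0.7], atol=1e-8)
        assert cp.hessian_signature == (1, 2)
        # 1-D scan oracle along the bond axis
        zs = np.linspace(0.55, 0.85, 2001)
        pts = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
        rho = density_at_points(hf.density, h2_sto3g.basis, pts)
        assert cp.rho == pytest.approx(rho.min(), abs=1e-6)

    def test_symmetry_gradient_vanishes_at_midpoint(self, h2_sto3g):
        hf = h2_sto3g.rhf()
        _, g, _ = rho_grad_hess(hf.density, h2_sto3g.basis,
                                np.array([0.0, 0.0, 0.7]))
        assert np.abs(g).max() < 1e-10

    def test_water_oh_bcp_found_with_correct_signature(self, water_sto3g):
        hf = water_sto3g.rhf()
        cp = find_bcp(hf.density, water_sto3g.basis, 0, 1)
        assert cp.hessian_signature == (1, 2)
        assert cp.gradient_norm < 1e-8
        # BCP lies close to the O-H axis
        mol = water_sto3g.molecule
        d = mol.coords[1] - mol.coords[0]
        t = np.dot(cp.position - mol.coords[0], d) / np.dot(d, d)
        off_axis = np.linalg.norm(cp.position - (mol.coords[0] + t * d))
        assert 0.0 < t < 1.0
        assert off_axis < 0.05

    def test_non_bcp_search_raises_with_signature(self, water_sto3g):
        # the H...H pair of water is not bonded: the stationary point
        # between the hydrogens is not a (3,-1) point
        hf = water_sto3g.rhf()
        with pytest.raises(BCPNotFound, match="signature"):
            find_bcp(hf.density, water_sto3g.basis, 1, 2)


class TestBondProfile:
    def test_h2_profile_symmetric_and_endpoints(self, h2_sto3g):
        hf = h2_sto3g.rhf()
        mol = h2_sto3g.molecule
        ts, rho = bond_profile(hf.density, h2_sto3g.basis,
                               mol.coords[0], mol.coords[1], 51)
        np.testing.assert_allclose(rho, rho[::-1], atol=1e-10)
        ends = density_at_points(hf.density, h2_sto3g.basis, mol.coords)
        assert rho[0] == pytest.approx(ends[0])
        assert rho[-1] == pytest.approx(ends[1])

    def test_two_point_profile_is_endpoint_pair(self, h2_sto3g):
        hf = h2_sto3g.rhf()
        mol = h2_sto3g.molecule
        _, rho = bond_profile(hf.density, h2_sto3g.basis,
                              mol.coords[0], mol.coords[1], 2)
        assert len(rho) == 2
        with pytest.raises(ValueError):
            bond_profile(hf.density, h2_sto3g.basis,
                         mol.coords[0], mol.coords[1], 1)


class TestGridConvergence:
    def test_richardson_refinement_shrinks_the_change(self, h2_sto3g):
        """Z_II and RSR converge as the spacing decreases."""
        hf = h2_sto3g.rhf()
        fci_like = 0.97 * hf.density  # any second field on the same grids
        vals = []
        for spacing in (0.6, 0.3, 0.15):
            grid = GridSpec.around(h2_sto3g.molecule, spacing, margin=4.0)
            f1 = density_on_grid(hf.density, h2_sto3g.basis, grid)
            vals.append(overlap_similarity(f1, f1))
        d1 = abs(vals[1] - vals[0])
        d2 = abs(vals[2] - vals[1])
        assert d2 < d1


class TestCubeIO:
    def test_round_trip(self, h2_sto3g, tmp_path):
        hf = h2_sto3g.rhf()
        grid = GridSpec.around(h2_sto3g.molecule, spacing=0.5, margin=2.0)
        f = density_on_grid(hf.density, h2_sto3g.basis, grid)
        path = tmp_path / "rho.cube"
        write_cube(f, h2_sto3g.molecule, path)
        back, mol = read_cube(path)
        assert back.grid.shape == grid.shape
        np.testing.assert_allclose(back.values, f.values, rtol=2e-5,
                                   atol=1e-10)
        np.testing.assert_allclose(mol.coords, h2_sto3g.molecule.coords,
                                   atol=1e-6)

    def test_header_counts_match_data(self, h2_sto3g, tmp_path):
        hf = h2_sto3g.rhf()
        grid = GridSpec.around(h2_sto3g.molecule, spacing=0.7, margin=1.5)
        f = density_on_grid(hf.density, h2_sto3g.basis, grid)
        path = tmp_path / "rho.cube"
        write_cube(f, h2_sto3g.molecule, path)
        lines = path.read_text().splitlines()
        natm = int(lines[2].split()[0])
        shape = [int(lines[3 + d].split()[0]) for d in range(3)]
        assert natm == 2
        n_values = sum(len(l.split()) for l in lines[6 + natm:])
        assert n_values == np.prod(shape)
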