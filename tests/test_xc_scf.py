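"""The constrained SCF: chi^2, functional, constraint term, solver, scans."""

import numpy as np
import pytest

from xcwfit import (ConstraintConfig, ElectronicStructure, Molecule,
                    XCRHFSolver, chi_squared, constraint_coefficients,
                    correlated_density, generate_reflection_set,
                    jayatilaka_functional, make_reference_amplitudes,
                    rhf_density)
from xcwfit.scf import fock_matrix


class TestChiSquared:
    def test_identical_sets_give_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert chi_squared(a, a) == 0.0

    def test_two_reflection_example(self):
        assert chi_squared([1.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_sigma_weighting(self):
        assert chi_squared([1.0, 2.0], [1.0, 1.0],
                           sigmas=[1.0, 2.0]) == pytest.approx(0.25)

    def test_requires_more_data_than_parameters(self):
        with pytest.raises(ValueError, match="N_r"):
            chi_squared([1.0], [1.0])


class TestFunctional:
    def test_lambda_zero_returns_energy(self):
        cfg = ConstraintConfig(lambda_J=0.0)
        assert jayatilaka_functional(-1.0, 123.4, cfg) == -1.0

    def test_weighted_example(self):
        cfg = ConstraintConfig(lambda_J=2.0, delta=1.0)
        assert jayatilaka_functional(-1.0, 1.5, cfg) == pytest.approx(0.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ConstraintConfig(lambda_J=-0.1)


class TestConstraintCoefficients:
    def test_perfect_fit_gives_zero_forces(self):
        F = np.array([1 + 1j, 2.0, -3.0j])
        K, _ = constraint_coefficients(F, np.abs(F), np.ones(3),
                                       ConstraintConfig())
        np.testing.assert_allclose(K, 0.0, atol=1e-15)

    def test_sigma_squared_scaling(self):
        F = np.array([2.0 + 0j, 1.0 + 1j, 0.5j])
        obs = np.array([1.5, 1.0, 1.0])
        cfg = ConstraintConfig()
        K1, _ = constraint_coefficients(F, obs, np.ones(3), cfg)
        K2, _ = constraint_coefficients(F, obs, 2.0 * np.ones(3), cfg)
        np.testing.assert_allclose(K2, K1 / 4.0)

    def test_phase_singular_reflections_damped(self, caplog):
        import logging

        F = np.array([1e-13 + 0j, 2.0 + 0j])
        with caplog.at_level(logging.WARNING):
            K, _ = constraint_coefficients(F, np.array([1.0, 1.0]),
                                           np.ones(2), ConstraintConfig())
        assert K[0] == 0.0
        assert "damped" in caplog.text


@pytest.fixture(scope="module")
def h2_fit_context(cell10):
    """H2 in the 10 A cell with FCI reference amplitudes (small basis)."""
    mol = Molecule([1, 1], [[0, 0, -0.7], [0, 0, 0.7]]).centered_in_cell(10.0)
    es = ElectronicStructure(mol, "6-31g")
    hf = rhf_density(mol, "6-31g", es)
    fci = correlated_density(mol, "6-31g", "FCI", es)
    refl = generate_reflection_set(cell10, 0.5)
    obs = make_reference_amplitudes(fci, refl)
    return mol, es, hf, fci, obs


class TestSolver:
    def test_lambda_zero_reduces_to_rhf(self, h2_fit_context):
        mol, es, hf, _, obs = h2_fit_context
        res = XCRHFSolver(mol, es.basis, obs).solve(0.0)
        assert res.e0 == pytest.approx(hf.energy, abs=1e-8)
        np.testing.assert_allclose(res.density_matrix, hf.P, atol=1e-6)

    def test_own_rhf_amplitudes_are_a_fixed_point(self, h2_fit_context,
                                                  cell10):
        mol, es, hf, _, _ = h2_fit_context
        refl = generate_reflection_set(cell10, 0.5)
        obs_rhf = make_reference_amplitudes(hf, refl)
        res = XCRHFSolver(mol, es.basis, obs_rhf).solve(8.0)
        assert res.chi2 < 1e-12
        np.testing.assert_allclose(res.density_matrix, hf.P, atol=5e-6)

    def test_gradient_consistency_finite_difference(self, h2_fit_context):
        """The constrained Fock matrix is the exact derivative of
        J = E0 + lambda chi^2 with respect to the density matrix."""
        mol, es, hf, _, obs = h2_fit_context
        solver = XCRHFSolver(mol, es.basis, obs)
        lam = 4.0
        rng = np.random.default_rng(11)
        P = hf.P + 0.02 * (lambda m: m + m.T)(rng.normal(size=hf.P.shape))

        def J(P):
            F = fock_matrix(solver.H, solver.eri, P)
            e0 = 0.5 * np.sum(P * (solver.H + F))
            return e0 + lam * solver.chi2(P)

        D = (lambda m: m + m.T)(rng.normal(size=hf.P.shape))
        eps = 1e-6
        fd = (J(P + eps * D) - J(P - eps * D)) / (2 * eps)
        F_c = fock_matrix(solver.H, solver.eri, P) \
            + solver.constraint_fock_term(P, lam)
        assert fd == pytest.approx(float(np.sum(F_c * D)), abs=1e-6)

    def test_constrained_fock_is_symmetric_and_lambda0_identity(
            self, h2_fit_context):
        mol, es, hf, _, obs = h2_fit_context
        solver = XCRHFSolver(mol, es.basis, obs)
        dF = solver.constraint_fock_term(hf.P, 3.0)
        assert np.abs(dF - dF.T).max() < 1e-12
        from xcwfit import build_constrained_fock

        F = fock_matrix(solver.H, solver.eri, hf.P)
        K, ph = constraint_coefficients(
            solver.blocks.contract(hf.P), solver.obs, solver.sigmas,
            solver.cfg)
        assert build_constrained_fock(F, solver.blocks, K, ph, 0.0) is F

    def test_delta_shift_cannot_change_the_minimizer(self, h2_fit_context):
        mol, es, _, _, obs = h2_fit_context
        r1 = XCRHFSolver(mol, es.basis, obs,
                         ConstraintConfig(delta=1.0)).solve(5.0)
        r2 = XCRHFSolver(mol, es.basis, obs,
                         ConstraintConfig(delta=7.5)).solve(5.0)
        np.testing.assert_allclose(r1.density_matrix, r2.density_matrix,
                                   atol=1e-8)
        assert r2.j_value == pytest.approx(r1.j_value - 5.0 * 6.5, abs=1e-7)

    def test_chi2_improves_on_rhf_for_positive_lambda(self, h2_fit_context):
        mol, es, hf, _, obs = h2_fit_context
        solver = XCRHFSolver(mol, es.basis, obs)
        chi2_rhf = solver.chi2(hf.P)
        res = solver.solve(5.0)
        assert res.converged
        assert res.chi2 < chi2_rhf

    def test_missing_amplitudes_rejected(self, h2_fit_context, cell10):
        mol, es, _, _, _ = h2_fit_context
        empty = generate_reflection_set(cell10, 0.3)
        with pytest.raises(ValueError, match="amplitude"):
            XCRHFSolver(mol, es.basis, empty)


class TestLambdaScan:
    def test_chi2_monotone_and_warm_equals_cold(self, h2_fit_context):
        mol, es, _, _, obs = h2_fit_context
        solver = XCRHFSolver(mol, es.basis, obs)
        scan = solver.scan([0.0, 0.5, 1.0, 2.0, 5.0, 10.0])
        chi2s = [r.chi2 for r in scan]
        assert all(b <= a + 1e-10 for a, b in zip(chi2s, chi2s[1:]))
        assert all(r.converged for r in scan)
        cold = solver.solve(10.0)
        np.testing.assert_allclose(cold.density_matrix,
                                   scan[-1].density_matrix, atol=1e-6)

    def test_descending_grid_rejected(self, h2_fit_context):
        mol, es, _, _, obs = h2_fit_context
        with pytest.raises(ValueError, match="ascending"):
            XCRHFSolver(mol, es.basis, obs).scan([1.0, 0.5])

    def test_single_point_grid_is_rhf(self, h2_fit_context):
        mol, es, hf, _, obs = h2_fit_context
        scan = XCRHFSolver(mol, es.basis, obs).scan([0.0])
        assert len(scan) == 1
        assert scan[0].e0 == pytest.approx(hf.energy, abs=1e-8)
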