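"""Structure factors: analytic FT blocks, toy closed forms, invariances."""

import numpy as np
import pytest

from xcwfit import (Molecule, ToyGaussianModel, amplitude_set,
                    ft_ao_pair_integrals, generate_reflection_set,
                    structure_factors_from_density,
                    toy_gaussian_structure_factor)
from xcwfit.constants import BOHR_PER_ANGSTROM
from xcwfit.integrals import ft_blocks_cart, core_hamiltonian


def _quadrature_ft(density_fn, k, lim=9.0, order=140):
    """Independent numerical Fourier transform: high-order Gauss-Legendre
    product quadrature of integral rho(r) exp(i k.r) dr over a cube that
    contains the density support to well below the assertion tolerance."""
    x, w = np.polynomial.legendre.leggauss(order)
    x = x * lim
    w = w * lim
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    rho = density_fn(pts)
    phase = np.exp(1j * (pts @ np.asarray(k, dtype=float)))
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).ravel()
    return complex(np.sum(W * rho * phase))


class TestToyModel:
    def test_zero_frequency_is_total_weight(self):
        m = ToyGaussianModel([[0, 0, 0]], [0.5], [2.0])
        assert toy_gaussian_structure_factor(m, [0, 0, 0]) == pytest.approx(2.0)

    def test_centrosymmetric_gaussian_is_real_positive(self):
        m = ToyGaussianModel([[0, 0, 0]], [0.9], [1.5])
        F = toy_gaussian_structure_factor(m, [0.3, -0.1, 0.2])
        assert abs(F.imag) < 1e-14
        assert F.real > 0

    def test_two_displaced_gaussians_match_quadrature(self):
        m = ToyGaussianModel([[0.5, -0.3, 0.2], [-0.8, 0.4, -0.1]],
                             [0.8, 1.3], [1.0, 2.0])
        q = np.array([0.12, 0.05, -0.07])  # angstrom^-1
        k = 2 * np.pi * q / BOHR_PER_ANGSTROM
        F_closed = toy_gaussian_structure_factor(m, q)
        F_quad = _quadrature_ft(m.density, k)
        assert abs(F_closed - F_quad) < 1e-10

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            ToyGaussianModel([[0, 0, 0]], [-0.5], [1.0])


class TestFTBlocks:
    def test_zero_frequency_block_is_overlap(self, h2_sto3g):
        S, _, _ = core_hamiltonian(h2_sto3g.basis)
        blk = ft_blocks_cart(*h2_sto3g.basis.packed(), np.zeros((1, 3)))
        S0 = h2_sto3g.basis.transform(blk[0].real)
        assert np.abs(blk[0].imag).max() < 1e-14
        np.testing.assert_allclose(S0, S, atol=1e-12)

    def test_friedel_blocks_are_conjugate(self, h2_sto3g):
        k = np.array([[0.3, -0.2, 0.5], [-0.3, 0.2, -0.5]])
        blk = ft_blocks_cart(*h2_sto3g.basis.packed(), k)
        np.testing.assert_allclose(blk[0], np.conj(blk[1]), atol=1e-14)

    def test_single_gaussian_diagonal_matches_quadrature(self):
        # one normalized s Gaussian: |g|^2 is again a normalized-times-
        # constant Gaussian; compare the analytic block entry at q with
        # adaptive 3-D quadrature
        mol = Molecule([1, 1], [[0, 0, 0], [0, 0, 50.0]])  # isolate atom 0
        from xcwfit.basis import BasisSet

        basis = BasisSet(mol, "sto-3g")
        q = np.array([0.15, 0.0, 0.1])  # angstrom^-1
        k = 2 * np.pi * q / BOHR_PER_ANGSTROM
        blk = ft_blocks_cart(*basis.packed(), k[None, :])
        analytic = basis.transform(blk[0].real)[0, 0] \
            + 1j * basis.transform(blk[0].imag)[0, 0]

        from xcwfit.integrals import ao_evaluate

        def dens(pts):
            vals, _, _ = ao_evaluate(basis, pts)
            return vals[:, 0] ** 2

        quad = _quadrature_ft(dens, k)
        assert abs(analytic - quad) < 1e-8


class TestStructureFactors:
    def test_f000_equals_electron_count(self, water_sto3g):
        hf = water_sto3g.rhf()
        blk = ft_blocks_cart(*water_sto3g.basis.packed(), np.zeros((1, 3)))
        S0 = water_sto3g.basis.transform(blk[0].real)
        assert np.sum(hf.density * S0) == pytest.approx(10.0, abs=1e-8)

    def test_zero_density_gives_zero(self, h2_sto3g, cell10):
        rs = generate_reflection_set(cell10, 0.1)
        blocks = ft_ao_pair_integrals(h2_sto3g.basis, rs)
        F = structure_factors_from_density(
            np.zeros_like(h2_sto3g.S), blocks)
        assert np.abs(F).max() == 0.0

    def test_contraction_linearity(self, h2_sto3g, cell10):
        rs = generate_reflection_set(cell10, 0.15)
        blocks = ft_ao_pair_integrals(h2_sto3g.basis, rs)
        rng = np.random.default_rng(3)
        P1 = rng.normal(size=h2_sto3g.S.shape)
        P1 = P1 + P1.T
        P2 = rng.normal(size=h2_sto3g.S.shape)
        P2 = P2 + P2.T
        F12 = structure_factors_from_density(P1 + P2, blocks)
        F1 = structure_factors_from_density(P1, blocks)
        F2 = structure_factors_from_density(P2, blocks)
        np.testing.assert_allclose(F12, F1 + F2, atol=1e-10)

    def test_origin_shift_changes_phases_not_amplitudes(self, cell10):
        from xcwfit import ElectronicStructure

        rs = generate_reflection_set(cell10, 0.2)
        mol1 = Molecule([1, 1], [[0, 0, 0], [0, 0, 1.4]])
        mol2 = mol1.translated([1.3, -0.7, 2.1])
        F = {}
        for tag, mol in [("a", mol1), ("b", mol2)]:
            es = ElectronicStructure(mol, "sto-3g")
            blocks = ft_ao_pair_integrals(es.basis, rs)
            F[tag] = structure_factors_from_density(es.rhf().density, blocks)
        assert not np.allclose(np.angle(F["a"]), np.angle(F["b"]))
        np.testing.assert_allclose(np.abs(F["a"]), np.abs(F["b"]), atol=1e-9)

    def test_asymmetric_density_rejected(self, h2_sto3g, cell10):
        rs = generate_reflection_set(cell10, 0.1)
        blocks = ft_ao_pair_integrals(h2_sto3g.basis, rs)
        P = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            structure_factors_from_density(P, blocks)


class TestAmplitudes:
    def test_modulus_and_scale(self):
        F = np.array([3 + 4j, -2.0, 0.0])
        np.testing.assert_allclose(amplitude_set(F), [5.0, 2.0, 0.0])
        np.testing.assert_allclose(amplitude_set(F, eta=2.0),
                                   [10.0, 4.0, 0.0])

    def test_empty_and_bad_eta(self):
        assert len(amplitude_set(np.array([]))) == 0
        with pytest.raises(ValueError):
            amplitude_set(np.array([1.0]), eta=0.0)


def test_correlated_minus_rhf_amplitudes_decay_with_resolution(
        h2_631g, cell10):
    """Amplitude differences concentrate at low angles and oscillate in
    sign (the qualitative signature of valence-only density changes)."""
    from xcwfit import correlated_density, make_reference_amplitudes, \
        rhf_density

    mol = h2_631g.molecule.centered_in_cell(10.0)
    from xcwfit import ElectronicStructure

    es = ElectronicStructure(mol, "6-31g")
    hf = rhf_density(mol, "6-31g", es)
    fci = correlated_density(mol, "6-31g", "FCI", es)
    rs = generate_reflection_set(cell10, 1.5)
    a_hf = make_reference_amplitudes(hf, rs)
    a_ci = make_reference_amplitudes(fci, rs)
    diff = a_ci.f_obs - a_hf.f_obs
    s = rs.s_array
    low = np.abs(diff[s <= 0.5]).max()
    high = np.abs(diff[s >= 1.0]).max()
    assert low > 3 * high
    assert (diff > 0).any() and (diff < 0).any()
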