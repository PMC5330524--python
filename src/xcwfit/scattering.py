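"""Structure factors from Gaussian densities.

The structure factor of the (P1) pseudo-crystal is the molecular form
factor F(h) = integral rho(r) exp(+2 pi i (B h).r) dr.  With rho expanded
in AO-pair densities this is a contraction of the density matrix with the
analytic plane-wave integral blocks

    I_h[mu, nu] = integral chi_mu(r) chi_nu(r) exp(2 pi i (B h).r) dr,

computed exactly by the McMurchie-Davidson machinery.  A closed-form toy
model (sums of normalized isotropic Gaussians) provides an independent
cross-check of the same quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
import hashlib
import os

import numpy as np

from .basis import BasisSet
from .constants import BOHR_PER_ANGSTROM
from .crystal import ReflectionSet, build_reciprocal_matrix
from .integrals import ft_blocks_cart


@dataclass
class FTIntegralBlocks:
    """Plane-wave AO-pair integrals for a reflection set.

    ``blocks_cart`` holds the raw-Cartesian matrices, shape
    (n_refl, ncart, ncart); densities are contracted against them after a
    congruence transform of P (cheaper than transforming every block).
    """

    reflection_set: ReflectionSet
    basis: BasisSet
    blocks_cart: np.ndarray

    def contract(self, P: np.ndarray) -> np.ndarray:
        """Complex F(h) for a density matrix P in the final AO basis."""
        C = self.basis.cart_to_final
        if P.shape != (self.basis.nbf, self.basis.nbf):
            raise ValueError(
                f"density matrix shape {P.shape} does not match basis "
                f"dimension {self.basis.nbf}")
        P_cart = C @ P @ C.T
        n = self.blocks_cart.shape[1]
        return self.blocks_cart.reshape(len(self.blocks_cart), n * n) \
            @ P_cart.reshape(-1)

    def weighted_matrix(self, weights: np.ndarray) -> np.ndarray:
        """Real symmetric AO matrix sum_h Re(w_h I_h) in the final basis.

        For the constrained Fock build pass complex weights
        w_h = lambda_J K_h exp(-i phi_h): the real part of w_h I_h is then
        K_h (cos phi Re I_h + sin phi Im I_h).
        """
        n = self.blocks_cart.shape[1]
        m_cart = (weights @ self.blocks_cart.reshape(len(weights), n * n)
                  ).reshape(n, n)
        C = self.basis.cart_to_final
        M = C.T @ m_cart.real @ C
        return 0.5 * (M + M.T)


def k_vectors(rset: ReflectionSet) -> np.ndarray:
    """Plane-wave vectors 2*pi*B*h in rad/bohr for every reflection."""
    B = build_reciprocal_matrix(rset.cell)  # angstrom^-1
    q = rset.hkl_array @ B.T                # angstrom^-1
    return 2.0 * np.pi * q / BOHR_PER_ANGSTROM


#: above this many complex block entries the blocks are stored in single
#: precision (the amplitude error is ~1e-6 relative, far below the
#: constraint's resolving power; the memory halves)
_SINGLE_PRECISION_THRESHOLD = 60_000_000

_CHUNK = 2048  # reflections per kernel call


def ft_ao_pair_integrals(basis: BasisSet, rset: ReflectionSet,
                         cache_dir: str | None = None,
                         dtype="auto") -> FTIntegralBlocks:
    """Analytic FT integral blocks for every reflection of the set.

    Computed in reflection batches to cap transient memory; for very large
    sets the stored blocks drop to single precision (``dtype='auto'``).
    Optionally cached on disk keyed by a content hash of (basis, geometry,
    cell, reflection list).
    """
    kv = np.ascontiguousarray(k_vectors(rset))
    nc = basis.n_cart_total
    if dtype == "auto":
        dtype = (np.complex64
                 if len(kv) * nc * nc > _SINGLE_PRECISION_THRESHOLD
                 else np.complex128)
    if cache_dir is not None:
        key = _content_key(basis, rset)
        path = os.path.join(cache_dir, f"ftblocks-{key}.npy")
        if os.path.exists(path):
            blocks = np.load(path)
            return FTIntegralBlocks(rset, basis, blocks)
    packed = basis.packed()
    blocks = np.empty((len(kv), nc, nc), dtype=dtype)
    for start in range(0, len(kv), _CHUNK):
        sl = slice(start, min(start + _CHUNK, len(kv)))
        blocks[sl] = ft_blocks_cart(*packed, kv[sl])
    if cache_dir is not None:
        os.makedirs(cache_dir, exist_ok=True)
        np.save(path, blocks)
    return FTIntegralBlocks(rset, basis, blocks)


def _content_key(basis: BasisSet, rset: ReflectionSet) -> str:
    h = hashlib.sha256()
    h.update(basis.name.encode())
    h.update(np.ascontiguousarray(basis.molecule.coords).tobytes())
    h.update(basis.molecule.atomic_numbers.tobytes())
    c = rset.cell
    h.update(np.array([c.a, c.b, c.c, c.alpha, c.beta, c.gamma]).tobytes())
    h.update(rset.hkl_array.tobytes())
    return h.hexdigest()[:16]


def structure_factors_from_density(P: np.ndarray,
                                   blocks: FTIntegralBlocks) -> np.ndarray:
    """Complex structure factors F(h) = sum_{mu nu} P_{mu nu} I_h,{mu nu}."""
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("density matrix must be symmetric")
    return blocks.contract(P)


def amplitude_set(f_values: np.ndarray, eta: float = 1.0) -> np.ndarray:
    """Amplitudes |eta F|; eta = 1 is the theoretical-constraint convention."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    return np.abs(np.asarray(f_values)) * eta


# --------------------------------------------------------------------------
# Toy model with closed-form transform
# --------------------------------------------------------------------------


@dataclass
class ToyGaussianModel:
    """Weighted sum of unit-integral isotropic Gaussians.

    rho(r) = sum_j w_j (alpha_j / pi)^{3/2} exp(-alpha_j |r - c_j|^2),
    centers in bohr, exponents in bohr^-2, weights in electrons.
    """

    centers: np.ndarray
    exponents: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.exponents = np.atleast_1d(np.asarray(self.exponents, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if np.any(self.exponents <= 0):
            raise ValueError("Gaussian exponents must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def density(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        rho = np.zeros(len(pts))
        for c, a, w in zip(self.centers, self.exponents, self.weights):
            d2 = np.sum((pts - c) ** 2, axis=1)
            rho += w * (a / np.pi) ** 1.5 * np.exp(-a * d2)
        return rho


def toy_gaussian_structure_factor(model: ToyGaussianModel,
                                  q_invang) -> complex:
    """Closed-form F(q) = sum_j w_j exp(2 pi i q.c_j) exp(-pi^2 |q|^2 / a_j).

    ``q_invang`` is the scattering vector B h in angstrom^-1 (centers are in
    bohr, so q is converted internally).
    """
    q = np.asarray(q_invang, dtype=float) / BOHR_PER_ANGSTROM  # bohr^-1
    k = 2.0 * np.pi * q                                        # rad/bohr
    k2 = float(k @ k)
    F = 0.0 + 0.0j
    for c, a, w in zip(model.centers, model.exponents, model.weights):
        F += w * np.exp(1j * float(k @ c)) * np.exp(-k2 / (4.0 * a))
    return complex(F)
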