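"""Reference densities and synthetic "observed" amplitude sets.

This is the data-generating stage of the study: it produces the geometries,
the uncorrelated (RHF) and correlated (FCI/CISD) one-particle density
matrices, and the theoretical structure-factor amplitude sets that the
constrained fit treats as observations.

The correlated benchmark of this package is CISD (variational; its
one-particle density is the plain expectation value over the CI vector,
``relaxed=False``).  FCI is available for small orbital spaces and is the
exact reference for two-electron systems, where CISD and FCI coincide.
Coupled-cluster and DFT densities are not provided by this implementation;
requesting them raises :class:`CapabilityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .basis import BasisSet
from .ci import cisd, determinant_ci
from .constants import BOHR_PER_ANGSTROM
from .crystal import ReflectionSet
from .integrals import core_hamiltonian, electron_repulsion
from .molecule import Molecule
from .scattering import amplitude_set, ft_ao_pair_integrals
from .scf import SCFResult, solve_rhf


class CapabilityError(NotImplementedError):
    """A requested electronic-structure method is not provided."""


# --------------------------------------------------------------------------
# Pinned fixture geometries
# --------------------------------------------------------------------------

#: Geometries pinned by this repository's own optimization runs (see the
#: ``provenance`` field of each entry).  Coordinates in bohr.
_A = BOHR_PER_ANGSTROM

_FIXTURES: dict[str, dict] = {
    "H2_test": dict(
        z=[1, 1],
        coords=[[0.0, 0.0, -0.7], [0.0, 0.0, 0.7]],
        charge=0,
        provenance="symmetric desk fixture, R = 1.4 bohr (not optimized)",
    ),
    "H2": dict(
        z=[1, 1],
        # R_e = 1.4023703 bohr, E = -1.17086459 hartree
        coords=[[0.0, 0.0, -0.7011852], [0.0, 0.0, 0.7011852]],
        charge=0,
        provenance="optimize_geometry FCI/6-311++G(2d,2p), Brent 1-D search",
    ),
    "N2": dict(
        z=[7, 7],
        # R_e = 2.0554197 bohr (1.0877 A), E = -109.33235062 hartree
        coords=[[0.0, 0.0, -1.0277098], [0.0, 0.0, 1.0277098]],
        charge=0,
        provenance="optimize_geometry CISD/6-311++G(2d,2p), Brent 1-D search",
    ),
    "CN-": dict(
        z=[6, 7],
        # R_e = 2.2078433 bohr (1.1683 A), E = -92.66865877 hartree
        coords=[[0.0, 0.0, -1.1039216], [0.0, 0.0, 1.1039216]],
        charge=-1,
        provenance="optimize_geometry CISD/6-311++G(2d,2p), Brent 1-D search",
    ),
    "water": dict(
        z=[8, 1, 1],
        # r(OH) = 1.7979 bohr (0.9514 A), HOH = 104.85 deg,
        # E = -76.31156325 hartree
        coords=[
            [0.0, 0.0, 0.0],
            [1.4249361, 0.0, -1.0963583],
            [-1.4249361, 0.0, -1.0963583],
        ],
        charge=0,
        provenance="optimize_geometry CISD/6-311++G(2d,2p), "
                   "C2v internal coordinates (Nelder-Mead)",
    ),
}


def fixture_geometry(name: str) -> Molecule:
    """A pinned molecular geometry with provenance metadata in the comment."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    f = _FIXTURES[name]
    return Molecule(np.array(f["z"]), np.array(f["coords"]),
                    charge=f["charge"], comment=f["provenance"])


# --------------------------------------------------------------------------
# Electronic-structure context
# --------------------------------------------------------------------------


@dataclass
class DensityMatrixResult:
    """A method-labelled one-particle density matrix in the AO basis."""

    method: str
    P: np.ndarray
    energy: float
    basis: BasisSet
    relaxed: bool = False

    def validate(self, S: np.ndarray | None = None, tol: float = 1e-6) -> None:
        """Trace and occupation-bound invariants."""
        if S is None:
            S, _, _ = core_hamiltonian(self.basis)
        n = self.basis.molecule.n_electrons
        tr = float(np.sum(self.P * S))
        if abs(tr - n) > 1e-8 * max(1, n):
            raise ValueError(f"trace(P S) = {tr} != {n}")
        s_eval, s_evec = np.linalg.eigh(S)
        X = s_evec @ np.diag(np.sqrt(np.abs(s_eval))) @ s_evec.T
        occ = np.linalg.eigvalsh(X @ self.P @ X)
        if occ.min() < -tol or occ.max() > 2.0 + tol:
            raise ValueError(
                f"natural occupations outside [0, 2]: [{occ.min()}, {occ.max()}]")


class ElectronicStructure:
    """Caches integrals and the RHF solution for one (molecule, basis)."""

    def __init__(self, molecule: Molecule, basis_name: str,
                 pure: bool = True):
        self.molecule = molecule
        self.basis = BasisSet(molecule, basis_name, pure=pure)
        self.S, T, V = core_hamiltonian(self.basis)
        self.H = T + V
        self._eri = None
        self._rhf: SCFResult | None = None

    @property
    def eri(self) -> np.ndarray:
        if self._eri is None:
            self._eri = electron_repulsion(self.basis)
        return self._eri

    def rhf(self) -> SCFResult:
        if self._rhf is None:
            self._rhf = solve_rhf(self.H, self.S, self.eri,
                                  self.molecule.n_electrons,
                                  self.molecule.nuclear_repulsion())
            if not self._rhf.converged:
                raise RuntimeError("RHF did not converge")
        return self._rhf

    def mo_integrals(self) -> tuple[np.ndarray, np.ndarray]:
        C = self.rhf().mo_coeff
        h_mo = C.T @ self.H @ C
        g_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", self.eri, C, C, C, C,
                         optimize=True)
        return h_mo, g_mo


def rhf_density(molecule: Molecule, basis_name: str,
                es: ElectronicStructure | None = None) -> DensityMatrixResult:
    """Converged restricted Hartree-Fock density."""
    es = es or ElectronicStructure(molecule, basis_name)
    res = es.rhf()
    out = DensityMatrixResult("RHF", res.density, res.energy, es.basis)
    out.validate(es.S)
    return out


#: FCI (dense determinant CI) is reserved for small determinant spaces.
_FCI_MAX_DETERMINANTS = 8000


def correlated_density(molecule: Molecule, basis_name: str, method: str,
                       es: ElectronicStructure | None = None
                       ) -> DensityMatrixResult:
    """Correlated one-particle density matrix (AO basis).

    method: "FCI" (determinant CI, small spaces only) or "CISD"
    (Davidson amplitude CI, any system the basis allows).  "CCSD" and DFT
    functionals are outside this implementation's capabilities.
    """
    method = method.upper()
    if method in ("CCSD",):
        raise CapabilityError(
            "CCSD densities are not provided by this implementation; "
            "CISD is the correlated benchmark here")
    if method.startswith("DFT") or method in ("BLYP", "B3LYP", "VSXC", "B1B95"):
        raise CapabilityError("DFT densities are not provided")
    if method not in ("FCI", "CISD"):
        raise ValueError(f"unknown correlated method {method!r}")
    es = es or ElectronicStructure(molecule, basis_name)
    hf = es.rhf()
    h_mo, g_mo = es.mo_integrals()
    n = molecule.n_electrons
    if method == "FCI":
        from math import comb

        ndet = comb(es.basis.nbf, n // 2) ** 2
        if ndet > _FCI_MAX_DETERMINANTS:
            raise ValueError(
                f"FCI determinant space of {ndet} exceeds the dense-CI limit "
                f"of {_FCI_MAX_DETERMINANTS}; use CISD")
        res = determinant_ci(h_mo, g_mo, n, molecule.nuclear_repulsion())
        dm_mo = res.rdm1_mo
        energy = res.energy
    else:
        res = cisd(h_mo, g_mo, n, hf.electronic_energy,
                   molecule.nuclear_repulsion())
        if not res.converged:
            raise RuntimeError("CISD Davidson iteration did not converge")
        dm_mo = res.rdm1_mo
        energy = res.energy
    C = hf.mo_coeff
    P_ao = C @ dm_mo @ C.T
    out = DensityMatrixResult(method, P_ao, energy, es.basis, relaxed=False)
    out.validate(es.S)
    return out


def dft_density(molecule: Molecule, basis_name: str, functional: str
                ) -> DensityMatrixResult:
    """Kohn-Sham densities are not within this implementation's scope."""
    raise CapabilityError(
        f"DFT functional {functional!r} requested, but no Kohn-Sham solver "
        "is provided by this package")


# --------------------------------------------------------------------------
# Reference amplitudes
# --------------------------------------------------------------------------


def make_reference_amplitudes(density: DensityMatrixResult,
                              reflections: ReflectionSet,
                              cache_dir: str | None = None) -> ReflectionSet:
    """Fill a reflection set with |F| computed from a density matrix.

    All sigmas are 1 (theoretical-constraint convention) and the origin
    reflection is excluded by construction of the set.
    """
    blocks = ft_ao_pair_integrals(density.basis, reflections, cache_dir)
    F = blocks.contract(density.P)
    return reflections.with_amplitudes(amplitude_set(F, eta=1.0), sigma=1.0)


# --------------------------------------------------------------------------
# Geometry optimization (numerical gradients over the delegated solvers)
# --------------------------------------------------------------------------


def _energy(molecule: Molecule, basis_name: str, method: str) -> float:
    es = ElectronicStructure(molecule, basis_name)
    if method.upper() == "RHF":
        return es.rhf().energy
    return correlated_density(molecule, basis_name, method, es).energy


def optimize_geometry(molecule: Molecule, basis_name: str,
                      method: str = "RHF", tol: float = 1e-5,
                      maxiter: int = 60) -> Molecule:
    """Minimize the total energy over nuclear coordinates.

    Diatomics reduce to a one-dimensional bond-length search (bracketed
    Brent); polyatomics use BFGS on Cartesian coordinates with central
    finite-difference gradients.  ``tol`` is the gradient norm target in
    hartree/bohr.
    """
    if molecule.natm == 2:
        direction = molecule.coords[1] - molecule.coords[0]
        r0 = float(np.linalg.norm(direction))
        u = direction / r0
        center = molecule.coords.mean(axis=0)

        def ener(r):
            coords = np.array([center - 0.5 * r * u, center + 0.5 * r * u])
            return _energy(Molecule(molecule.atomic_numbers, coords,
                                    molecule.charge), basis_name, method)

        res = scipy.optimize.minimize_scalar(
            ener, bracket=(0.8 * r0, r0, 1.2 * r0),
            options={"xtol": 1e-5})
        r = float(res.x)
        coords = np.array([center - 0.5 * r * u, center + 0.5 * r * u])
        return Molecule(molecule.atomic_numbers, coords, molecule.charge,
                        comment=f"optimized {method}/{basis_name}")

    x0 = molecule.coords.ravel().copy()

    def fun(x):
        return _energy(Molecule(molecule.atomic_numbers, x.reshape(-1, 3),
                                molecule.charge), basis_name, method)

    res = scipy.optimize.minimize(
        fun, x0, method="BFGS",
        options={"gtol": tol, "maxiter": maxiter, "eps": 5e-4})
    if not res.success and np.linalg.norm(res.jac, np.inf) > 10 * tol:
        raise RuntimeError(f"geometry optimization did not converge: "
                           f"{res.message}")
    return Molecule(molecule.atomic_numbers, res.x.reshape(-1, 3),
                    molecule.charge,
                    comment=f"optimized {method}/{basis_name}")
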