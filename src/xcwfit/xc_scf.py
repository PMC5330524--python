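"""X-ray constrained restricted Hartree-Fock.

The constrained single determinant minimizes the functional

    J[Phi] = E0[Phi] + lambda_J * (chi2[Phi] - Delta),

with the agreement statistic over N_r reflections and N_p (=1) adjustable
parameters

    chi2 = 1/(N_r - N_p) * sum_h (eta |F_h^calc| - |F_h^obs|)^2 / sigma_h^2.

Stationarity leads to a modified Roothaan problem in which the Fock
operator acquires the structure-factor penalty term

    F_J = F + lambda_J * sum_h K_h * Re[exp(-i phi_h) I_h],
    K_h = 2 eta (eta |F_h| - |F_h^obs|) / (sigma_h^2 (N_r - N_p)),

where phi_h is the phase of the calculated structure factor; this is the
exact derivative of lambda_J * chi2 with respect to the density matrix, so
the self-consistent solution is the constrained minimizer.  Reflections
with |F_h| below a phase tolerance contribute no constraint force for that
iteration (their phase is undefined); this is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .basis import BasisSet
from .crystal import ReflectionSet
from .integrals import core_hamiltonian, electron_repulsion
from .molecule import Molecule
from .scattering import FTIntegralBlocks, ft_ao_pair_integrals
from .scf import solve_rhf

logger = logging.getLogger(__name__)

#: below this calculated amplitude a reflection's phase is undefined and its
#: constraint contribution is damped to zero for the iteration
PHASE_TOLERANCE = 1e-10


@dataclass(frozen=True)
class ConstraintConfig:
    """Settings of the reciprocal-space constraint.

    With purely theoretical reference amplitudes the study convention is
    sigma_h = 1, eta = 1 (never refined) and N_p = 1 (the external
    multiplier is the only adjustable parameter, also at lambda_J = 0).
    Delta shifts J by a constant and cannot affect the minimizer.
    """

    lambda_J: float = 0.0
    delta: float = 1.0
    eta: float = 1.0
    n_params: int = 1

    def __post_init__(self):
        if self.lambda_J < 0:
            raise ValueError("lambda_J must be nonnegative")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass
class XCWFResult:
    """Converged state of one constrained-SCF solution."""

    mo_coefficients: np.ndarray
    density_matrix: np.ndarray
    e0: float                 # HF energy functional at the XC density (total)
    chi2: float
    j_value: float            # E0 + lambda_J (chi2 - Delta)
    lambda_J: float
    s_max: float
    n_iterations: int
    converged: bool
    mo_energies: np.ndarray | None = None
    history: list = field(default_factory=list)


def chi_squared(calc_amplitudes, obs_amplitudes, sigmas=None,
                eta: float = 1.0, n_params: int = 1) -> float:
    """Normalized amplitude agreement statistic."""
    calc = np.asarray(calc_amplitudes, dtype=float)
    obs = np.asarray(obs_amplitudes, dtype=float)
    if calc.shape != obs.shape:
        raise ValueError("amplitude lists must have equal length")
    n_r = len(calc)
    if n_r <= n_params:
        raise ValueError(f"need N_r > N_p, got N_r={n_r}, N_p={n_params}")
    sig = np.ones(n_r) if sigmas is None else np.asarray(sigmas, dtype=float)
    resid = (eta * calc - obs) / sig
    return float(resid @ resid) / (n_r - n_params)


def jayatilaka_functional(e0: float, chi2: float, cfg: ConstraintConfig) -> float:
    """J = E0 + lambda_J (chi2 - Delta)."""
    return e0 + cfg.lambda_J * (chi2 - cfg.delta)


def constraint_coefficients(f_calc: np.ndarray, obs_amplitudes, sigmas,
                            cfg: ConstraintConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-reflection K_h and phase factors exp(-i phi_h).

    Returns (K, phase_conj); K_h is zero exactly where the residual
    vanishes, and also (with a log message) where |F_calc| is below the
    phase tolerance.
    """
    f_calc = np.asarray(f_calc)
    obs = np.asarray(obs_amplitudes, dtype=float)
    sig = np.asarray(sigmas, dtype=float)
    n_r = len(f_calc)
    amp = np.abs(f_calc)
    K = 2.0 * cfg.eta * (cfg.eta * amp - obs) / (sig ** 2 * (n_r - cfg.n_params))
    singular = amp < PHASE_TOLERANCE
    if np.any(singular):
        logger.warning(
            "%d reflections with |F_calc| < %.1e: constraint contribution "
            "damped to zero this iteration", int(singular.sum()), PHASE_TOLERANCE)
    phase_conj = np.ones(n_r, dtype=complex)
    ok = ~singular
    phase_conj[ok] = np.conj(f_calc[ok]) / amp[ok]
    K[singular] = 0.0
    return K, phase_conj


def build_constrained_fock(fock: np.ndarray, blocks: FTIntegralBlocks,
                           K: np.ndarray, phase_conj: np.ndarray,
                           lambda_J: float) -> np.ndarray:
    """Fock-Jayatilaka matrix F + lambda_J sum_h K_h Re[e^{-i phi} I_h]."""
    if lambda_J == 0.0:
        return fock
    return fock + blocks.weighted_matrix(lambda_J * K * phase_conj)


class XCRHFSolver:
    """Holds the molecule-, basis- and reflection-specific context.

    Integrals are computed once; :meth:`solve` then runs a constrained SCF
    for a given lambda_J, optionally warm-started, and :meth:`scan` walks an
    ascending lambda grid reusing the previous density.
    """

    def __init__(self, molecule: Molecule, basis: BasisSet,
                 reflections: ReflectionSet,
                 cfg: ConstraintConfig = ConstraintConfig(),
                 cache_dir: str | None = None,
                 conv_tol_grad: float = 1e-7,
                 conv_tol_energy: float = 1e-8,
                 max_iter: int = 300):
        if len(reflections) <= cfg.n_params:
            raise ValueError("need more reflections than adjustable parameters")
        if np.any(np.isnan(reflections.f_obs)):
            raise ValueError("reflection set carries no observed amplitudes")
        self.molecule = molecule
        self.basis = basis
        self.reflections = reflections
        self.cfg = cfg
        self.conv_tol_grad = conv_tol_grad
        self.conv_tol_energy = conv_tol_energy
        self.max_iter = max_iter
        self.S, T, V = core_hamiltonian(basis)
        self.H = T + V
        self.eri = electron_repulsion(basis)
        self.e_nuc = molecule.nuclear_repulsion()
        self.blocks = ft_ao_pair_integrals(basis, reflections, cache_dir)
        self.obs = reflections.f_obs
        self.sigmas = reflections.sigmas

    # ------------------------------------------------------------------
    def amplitudes(self, P: np.ndarray) -> np.ndarray:
        return np.abs(self.blocks.contract(P))

    def chi2(self, P: np.ndarray) -> float:
        return chi_squared(self.amplitudes(P), self.obs, self.sigmas,
                           self.cfg.eta, self.cfg.n_params)

    def constraint_fock_term(self, P: np.ndarray, lambda_J: float) -> np.ndarray:
        f_calc = self.blocks.contract(P)
        K, phase_conj = constraint_coefficients(
            f_calc, self.obs, self.sigmas, self.cfg)
        return self.blocks.weighted_matrix(lambda_J * K * phase_conj)

    # ------------------------------------------------------------------
    def solve(self, lambda_J: float,
              initial_density: np.ndarray | None = None) -> XCWFResult:
        cfg = replace(self.cfg, lambda_J=lambda_J)
        modifier = None
        if lambda_J > 0.0:
            def modifier(P):
                return self.constraint_fock_term(P, lambda_J)
        res = solve_rhf(
            self.H, self.S, self.eri, self.molecule.n_electrons,
            self.e_nuc, fock_modifier=modifier,
            initial_density=initial_density,
            conv_tol_grad=self.conv_tol_grad,
            conv_tol_energy=self.conv_tol_energy,
            max_iter=self.max_iter)
        if not res.converged:
            logger.warning(
                "DIIS did not converge at lambda_J=%.2f (err %.2e); "
                "retrying with density damping", lambda_J, res.error_norm)
            res = solve_rhf(
                self.H, self.S, self.eri, self.molecule.n_electrons,
                self.e_nuc, fock_modifier=modifier,
                initial_density=res.density,
                conv_tol_grad=self.conv_tol_grad,
                conv_tol_energy=self.conv_tol_energy,
                max_iter=2 * self.max_iter, damping=0.35)
        chi2 = self.chi2(res.density)
        return XCWFResult(
            mo_coefficients=res.mo_coeff,
            density_matrix=res.density,
            e0=res.energy,
            chi2=chi2,
            j_value=jayatilaka_functional(res.energy, chi2, cfg),
            lambda_J=lambda_J,
            s_max=self.reflections.s_max,
            n_iterations=res.n_iter,
            converged=res.converged,
            mo_energies=res.mo_energy,
            history=res.history,
        )

    def scan(self, lambda_grid) -> list[XCWFResult]:
        """Warm-started ascending lambda_J scan."""
        grid = list(lambda_grid)
        if any(b < a for a, b in zip(grid, grid[1:])):
            raise ValueError("lambda grid must be ascending")
        results = []
        P = None
        for lam in grid:
            res = self.solve(lam, initial_density=P)
            if results and res.converged and results[-1].converged \
                    and res.chi2 > results[-1].chi2 + 1e-10:
                logger.warning(
                    "chi2 increased along the scan at lambda_J=%.2f "
                    "(%.6e -> %.6e): flagging as convergence failure",
                    lam, results[-1].chi2, res.chi2)
                res.converged = False
            results.append(res)
            P = res.density_matrix
        return results


def xc_scf_solve(molecule: Molecule, basis: BasisSet,
                 reflections: ReflectionSet,
                 cfg: ConstraintConfig = ConstraintConfig(),
                 initial_density: np.ndarray | None = None) -> XCWFResult:
    """One-shot constrained SCF (convenience wrapper around XCRHFSolver)."""
    solver = XCRHFSolver(molecule, basis, reflections, cfg)
    return solver.solve(cfg.lambda_J, initial_density)


def lambda_scan(molecule: Molecule, basis: BasisSet,
                reflections: ReflectionSet, lambda_grid,
                cfg: ConstraintConfig = ConstraintConfig()) -> list[XCWFResult]:
    """Warm-started scan over an ascending lambda_J grid."""
    solver = XCRHFSolver(molecule, basis, reflections, cfg)
    return solver.scan(lambda_grid)
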