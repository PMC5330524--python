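"""Restricted Hartree-Fock with DIIS convergence acceleration.

The same Roothaan driver serves the unconstrained reference calculation and
the reciprocal-space-constrained fit: the constrained solver passes a
callback that augments the Fock matrix with the structure-factor penalty
term at each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SCFResult:
    energy: float            # total energy incl. nuclear repulsion, hartree
    electronic_energy: float
    mo_coeff: np.ndarray     # (nbf, nbf)
    mo_energy: np.ndarray
    density: np.ndarray      # total density matrix P, trace(P S) = n_elec
    fock: np.ndarray
    converged: bool
    n_iter: int
    error_norm: float
    history: list = field(default_factory=list)


def density_from_mo(C: np.ndarray, nocc: int) -> np.ndarray:
    Cocc = C[:, :nocc]
    return 2.0 * Cocc @ Cocc.T


def fock_matrix(H: np.ndarray, eri: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Closed-shell Fock matrix F = H + J - K/2 built from the total P."""
    nbf = len(H)
    g = eri.reshape(nbf * nbf, nbf * nbf)
    J = (g @ P.reshape(-1)).reshape(nbf, nbf)
    # K_{mu nu} = sum_{la si} (mu la | si nu) P_{la si}
    K = np.einsum("mlsn,ls->mn", eri, P, optimize=True)
    return H + J - 0.5 * K


def electronic_energy(H: np.ndarray, F: np.ndarray, P: np.ndarray) -> float:
    return 0.5 * float(np.sum(P * (H + F)))


class DIIS:
    """Pulay DIIS over Fock matrices with the commutator error vector."""

    def __init__(self, max_vec: int = 8):
        self.max_vec = max_vec
        self.focks: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def update(self, F: np.ndarray, err: np.ndarray) -> np.ndarray:
        self.focks.append(F.copy())
        self.errors.append(err.ravel().copy())
        if len(self.focks) > self.max_vec:
            self.focks.pop(0)
            self.errors.pop(0)
        n = len(self.focks)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.errors[i] @ self.errors[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            coef = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            self.focks = self.focks[-1:]
            self.errors = self.errors[-1:]
            return F
        return sum(c * f for c, f in zip(coef, self.focks))


def solve_rhf(
    H: np.ndarray,
    S: np.ndarray,
    eri: np.ndarray,
    n_electrons: int,
    e_nuc: float = 0.0,
    fock_modifier=None,
    initial_density: np.ndarray | None = None,
    conv_tol_grad: float = 1e-7,
    conv_tol_energy: float = 1e-9,
    max_iter: int = 300,
    diis_start: int = 2,
    damping: float = 0.0,
) -> SCFResult:
    """Solve the (possibly modified) Roothaan equations.

    ``fock_modifier(P) -> (dF, extra_info)`` returns an additive, symmetric
    correction to the Fock matrix evaluated at the current density; the
    correction must be the derivative of the extra objective term with
    respect to P so that the stationary point is the constrained minimum.
    """
    if n_electrons % 2 != 0:
        raise ValueError("closed-shell solver requires an even electron count")
    nocc = n_electrons // 2
    nbf = len(H)
    # symmetric orthogonalization with eigenvalue screening for near-linear
    # dependence (diffuse Pople sets can be marginally redundant)
    s_eval, s_evec = np.linalg.eigh(S)
    keep = s_eval > 1e-9
    X = s_evec[:, keep] / np.sqrt(s_eval[keep])

    if initial_density is None:
        # core guess
        Fp = X.T @ H @ X
        _, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        P = density_from_mo(C, nocc)
    else:
        P = initial_density.copy()

    diis = DIIS()
    e_old = 0.0
    history = []
    converged = False
    err_norm = np.inf
    F = H.copy()
    for it in range(1, max_iter + 1):
        F_pure = fock_matrix(H, eri, P)
        F = F_pure if fock_modifier is None else F_pure + fock_modifier(P)
        err = X.T @ (F @ P @ S - S @ P @ F) @ X
        err_norm = np.linalg.norm(err) / max(1, nbf)
        F_eff = F
        if it >= diis_start:
            F_eff = diis.update(F, err)
        Fp = X.T @ F_eff @ X
        mo_e, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        P_new = density_from_mo(C, nocc)
        if damping > 0.0 and it > 1:
            P_new = (1.0 - damping) * P_new + damping * P
        e_elec = electronic_energy(H, F_pure, P)
        de = e_elec - e_old
        history.append((it, e_elec + e_nuc, err_norm))
        if err_norm < conv_tol_grad and abs(de) < conv_tol_energy and it > 1:
            converged = True
            break
        e_old = e_elec
        P = P_new

    # final consistent quantities at the converged density
    F = fock_matrix(H, eri, P)
    if fock_modifier is not None:
        F = F + fock_modifier(P)
    Fp = X.T @ F @ X
    mo_e, Cp = np.linalg.eigh(Fp)
    C_full = X @ Cp
    e_elec = electronic_energy(H, fock_matrix(H, eri, P), P)
    return SCFResult(
        energy=e_elec + e_nuc,
        electronic_energy=e_elec,
        mo_coeff=C_full,
        mo_energy=mo_e,
        density=P,
        fock=F,
        converged=converged,
        n_iter=it,
        error_norm=err_norm,
        history=history,
    )
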