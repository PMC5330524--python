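"""Attachment/detachment decomposition of a density-matrix difference.

The difference between a correlated (or constrained) density matrix and the
RHF "pseudo-ground-state" density is diagonalized in the Loewdin
orthonormalized basis; negative eigenmodes collect into the detachment
density D, positive ones into the attachment density A, so that

    A - D = P_corr - P_ref      (exactly),
    p = tr(A S) = tr(D S)       (the number of promoted electrons,
                                 when both densities share the electron count).

The study repurposes this excited-state tool to measure how much electronic
reorganization a correlated or X-ray constrained density represents
relative to RHF: a smaller p means a milder reorganization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet
from .density_metrics import GridSpec, ScalarField, density_on_grid


@dataclass
class AttachDetachResult:
    detachment: np.ndarray   # AO basis, positive semidefinite (w.r.t. S)
    attachment: np.ndarray
    promoted_electrons: float

    def difference(self) -> np.ndarray:
        return self.attachment - self.detachment


def attach_detach_decomposition(P_ref: np.ndarray, P_corr: np.ndarray,
                                S: np.ndarray) -> AttachDetachResult:
    """Split P_corr - P_ref into attachment and detachment parts."""
    if P_ref.shape != P_corr.shape:
        raise ValueError("density matrices must share the AO basis")
    tr_ref = float(np.sum(P_ref * S))
    tr_corr = float(np.sum(P_corr * S))
    if abs(tr_ref - tr_corr) > 1e-6:
        raise ValueError(
            f"electron-count mismatch: tr(P_ref S) = {tr_ref:.8f}, "
            f"tr(P_corr S) = {tr_corr:.8f}")
    s_eval, s_evec = np.linalg.eigh(S)
    if s_eval.min() <= 0:
        raise ValueError("overlap matrix is not positive definite")
    S_half = s_evec @ np.diag(np.sqrt(s_eval)) @ s_evec.T
    S_mhalf = s_evec @ np.diag(1.0 / np.sqrt(s_eval)) @ s_evec.T
    delta = S_half @ (P_corr - P_ref) @ S_half
    evals, evecs = np.linalg.eigh(0.5 * (delta + delta.T))
    pos = evals > 0
    A_orth = (evecs[:, pos] * evals[pos]) @ evecs[:, pos].T
    D_orth = -(evecs[:, ~pos] * evals[~pos]) @ evecs[:, ~pos].T
    A = S_mhalf @ A_orth @ S_mhalf
    D = S_mhalf @ D_orth @ S_mhalf
    p = float(evals[pos].sum())
    return AttachDetachResult(detachment=D, attachment=A,
                              promoted_electrons=p)


def attach_detach_fields(result: AttachDetachResult, basis: BasisSet,
                         grid: GridSpec | None = None
                         ) -> tuple[ScalarField, ScalarField]:
    """Attachment and detachment densities on a real-space grid."""
    grid = grid or GridSpec.around(basis.molecule)
    fa = density_on_grid(result.attachment, basis, grid)
    fd = density_on_grid(result.detachment, basis, grid)
    return fa, fd
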