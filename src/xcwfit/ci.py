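"""Configuration-interaction wavefunctions and one-particle densities.

Two complementary engines:

* a determinant-basis CI (bitstring Slater-Condon rules, dense
  diagonalization) usable for FCI in small orbital spaces and for
  excitation-capped CI (CIS, CISD, ...) as a brute-force reference;
* a spin-orbital amplitude CISD (Davidson iteration over the
  {reference, singles, doubles} block structure) that scales to the
  production basis sets.

Both return the spin-summed one-particle density matrix in the MO basis;
the two routes agree to tight tolerance on overlapping systems, which is
asserted in the test suite.  For two-electron systems CISD coincides with
FCI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

# ==========================================================================
# Determinant CI
# ==========================================================================


@njit(cache=True)
def _popcount(x: np.int64) -> int:
    n = 0
    while x:
        x &= x - np.int64(1)
        n += 1
    return n


@njit(cache=True)
def _occ_list(string: np.int64, nmo: int, out):
    n = 0
    for p in range(nmo):
        if string & (np.int64(1) << p):
            out[n] = p
            n += 1
    return n


@njit(cache=True)
def _single_phase(string: np.int64, i: int, a: int) -> float:
    """Sign of a_i -> a_a applied to |string> (i occupied, a virtual)."""
    lo, hi = (i, a) if i < a else (a, i)
    mask = np.int64(0)
    for p in range(lo + 1, hi):
        mask |= np.int64(1) << p
    return -1.0 if (_popcount(string & mask) % 2) else 1.0


@njit(cache=True)
def _excitation(s1: np.int64, s2: np.int64):
    """(degree, holes in s1, particles in s2) for one spin string."""
    diff = s1 ^ s2
    holes = s1 & diff
    parts = s2 & diff
    return _popcount(diff) // 2, holes, parts


@njit(cache=True)
def _bits(x: np.int64, nmo: int, out):
    n = 0
    for p in range(nmo):
        if x & (np.int64(1) << p):
            out[n] = p
            n += 1
    return n


@njit(cache=True)
def _slater_condon(a1, b1, a2, b2, nmo, h, g):
    """<D1|H|D2> with spatial MO integrals h[p,q] and chemists' g[p,q,r,s]."""
    da, ha, pa = _excitation(a1, a2)
    db, hb, pb = _excitation(b1, b2)
    deg = da + db
    if deg > 2:
        return 0.0
    occ_a = np.empty(nmo, dtype=np.int64)
    occ_b = np.empty(nmo, dtype=np.int64)
    na = _occ_list(a1, nmo, occ_a)
    nb = _occ_list(b1, nmo, occ_b)
    if deg == 0:
        e = 0.0
        for ii in range(na):
            e += h[occ_a[ii], occ_a[ii]]
        for ii in range(nb):
            e += h[occ_b[ii], occ_b[ii]]
        for ii in range(na):
            for jj in range(na):
                i = occ_a[ii]
                j = occ_a[jj]
                e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
        for ii in range(nb):
            for jj in range(nb):
                i = occ_b[ii]
                j = occ_b[jj]
                e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
        for ii in range(na):
            for jj in range(nb):
                e += g[occ_a[ii], occ_a[ii], occ_b[jj], occ_b[jj]]
        return e
    if deg == 1:
        tmp = np.empty(2, dtype=np.int64)
        if da == 1:
            _bits(ha, nmo, tmp)
            i = tmp[0]
            _bits(pa, nmo, tmp)
            a = tmp[0]
            ph = _single_phase(a1, i, a)
            e = h[i, a]
            for jj in range(na):
                j = occ_a[jj]
                if j != i:
                    e += g[i, a, j, j] - g[i, j, j, a]
            for jj in range(nb):
                j = occ_b[jj]
                e += g[i, a, j, j]
            return ph * e
        else:
            _bits(hb, nmo, tmp)
            i = tmp[0]
            _bits(pb, nmo, tmp)
            a = tmp[0]
            ph = _single_phase(b1, i, a)
            e = h[i, a]
            for jj in range(nb):
                j = occ_b[jj]
                if j != i:
                    e += g[i, a, j, j] - g[i, j, j, a]
            for jj in range(na):
                j = occ_a[jj]
                e += g[i, a, j, j]
            return ph * e
    # deg == 2
    tmp = np.empty(2, dtype=np.int64)
    if da == 2:
        n = _bits(ha, nmo, tmp)
        i, j = tmp[0], tmp[1]
        n = _bits(pa, nmo, tmp)
        a, b = tmp[0], tmp[1]
        # sequential application: i->a then j->b on the intermediate string
        ph = _single_phase(a1, i, a)
        inter = (a1 ^ (np.int64(1) << i)) | (np.int64(1) << a)
        ph *= _single_phase(inter, j, b)
        return ph * (g[i, a, j, b] - g[i, b, j, a])
    if db == 2:
        n = _bits(hb, nmo, tmp)
        i, j = tmp[0], tmp[1]
        n = _bits(pb, nmo, tmp)
        a, b = tmp[0], tmp[1]
        ph = _single_phase(b1, i, a)
        inter = (b1 ^ (np.int64(1) << i)) | (np.int64(1) << a)
        ph *= _single_phase(inter, j, b)
        return ph * (g[i, a, j, b] - g[i, b, j, a])
    # one alpha + one beta
    _bits(ha, nmo, tmp)
    i = tmp[0]
    _bits(pa, nmo, tmp)
    a = tmp[0]
    ph = _single_phase(a1, i, a)
    _bits(hb, nmo, tmp)
    j = tmp[0]
    _bits(pb, nmo, tmp)
    b = tmp[0]
    ph *= _single_phase(b1, j, b)
    return ph * g[i, a, j, b]


@njit(cache=True)
def _build_h(alphas, betas, nmo, h, g):
    nd = len(alphas)
    H = np.zeros((nd, nd))
    for I in range(nd):
        for J in range(I, nd):
            da = _popcount(alphas[I] ^ alphas[J])
            db = _popcount(betas[I] ^ betas[J])
            if da + db > 4:
                continue
            v = _slater_condon(alphas[I], betas[I], alphas[J], betas[J],
                               nmo, h, g)
            H[I, J] = v
            H[J, I] = v
    return H


@njit(cache=True)
def _rdm1(alphas, betas, civec, nmo):
    """Spin-summed 1-RDM in the MO basis from a determinant CI vector."""
    nd = len(alphas)
    dm = np.zeros((nmo, nmo))
    occ = np.empty(nmo, dtype=np.int64)
    tmp = np.empty(2, dtype=np.int64)
    for I in range(nd):
        cI = civec[I]
        if cI == 0.0:
            continue
        # diagonal occupations
        n = _occ_list(alphas[I], nmo, occ)
        for ii in range(n):
            dm[occ[ii], occ[ii]] += cI * cI
        n = _occ_list(betas[I], nmo, occ)
        for ii in range(n):
            dm[occ[ii], occ[ii]] += cI * cI
        for J in range(nd):
            if I == J:
                continue
            da = _popcount(alphas[I] ^ alphas[J]) // 2
            db = _popcount(betas[I] ^ betas[J]) // 2
            if da + db != 1:
                continue
            cJ = civec[J]
            if cJ == 0.0:
                continue
            if da == 1:
                _, h_, p_ = _excitation(alphas[I], alphas[J])
                _bits(h_, nmo, tmp)
                q = tmp[0]   # occupied in I
                _bits(p_, nmo, tmp)
                p = tmp[0]   # occupied in J
                ph = _single_phase(alphas[I], q, p)
                dm[q, p] += ph * cI * cJ
            else:
                _, h_, p_ = _excitation(betas[I], betas[J])
                _bits(h_, nmo, tmp)
                q = tmp[0]
                _bits(p_, nmo, tmp)
                p = tmp[0]
                ph = _single_phase(betas[I], q, p)
                dm[q, p] += ph * cI * cJ
    return dm


def _strings(nmo: int, nocc: int) -> list[int]:
    """All nmo-choose-nocc occupation bitstrings, ascending."""
    from itertools import combinations

    out = []
    for occ in combinations(range(nmo), nocc):
        s = 0
        for p in occ:
            s |= 1 << p
        out.append(s)
    return sorted(out)


@dataclass
class DeterminantCIResult:
    energy: float               # total electronic + nuclear energy if e_nuc given
    correlation_energy: float
    civec: np.ndarray
    rdm1_mo: np.ndarray         # spin-summed, MO basis
    n_determinants: int


def determinant_ci(h_mo: np.ndarray, g_mo: np.ndarray, n_electrons: int,
                   e_nuc: float = 0.0, max_excitation: int | None = None,
                   e_ref: float | None = None) -> DeterminantCIResult:
    """Dense CI in the determinant basis (FCI, or capped at an excitation
    level relative to the closed-shell reference determinant)."""
    nmo = len(h_mo)
    if nmo > 62:
        raise ValueError("determinant CI limited to <= 62 orbitals")
    nocc = n_electrons // 2
    if 2 * nocc != n_electrons:
        raise ValueError("closed-shell electron count required")
    strings = _strings(nmo, nocc)
    ref = (1 << nocc) - 1
    dets = []
    for sa in strings:
        for sb in strings:
            if max_excitation is not None:
                exc = (bin(sa ^ ref).count("1") + bin(sb ^ ref).count("1")) // 2
                if exc > max_excitation:
                    continue
            dets.append((sa, sb))
    # reference determinant first (deterministic ordering otherwise)
    dets.sort(key=lambda d: (d != (ref, ref), d))
    alphas = np.array([d[0] for d in dets], dtype=np.int64)
    betas = np.array([d[1] for d in dets], dtype=np.int64)
    H = _build_h(alphas, betas, nmo, h_mo, g_mo)
    evals, evecs = np.linalg.eigh(H)
    civec = evecs[:, 0]
    if civec[0] < 0:
        civec = -civec
    dm = _rdm1(alphas, betas, civec, nmo)
    e_elec = float(evals[0])
    e_hf = float(H[0, 0]) if e_ref is None else e_ref
    return DeterminantCIResult(
        energy=e_elec + e_nuc,
        correlation_energy=e_elec - e_hf,
        civec=civec,
        rdm1_mo=0.5 * (dm + dm.T),
        n_determinants=len(dets),
    )


# ==========================================================================
# Spin-orbital amplitude CISD (Davidson)
# ==========================================================================


class _SpinBlocks:
    """Antisymmetrized spin-orbital integral blocks <pq||rs> from spatial
    chemists' integrals, with the [alpha(0..n-1) | beta(n..2n-1)] layout
    folded down to blocked (occ, virt) index groups."""

    def __init__(self, g_mo: np.ndarray, fock_diag: np.ndarray, nocc: int):
        nmo = len(fock_diag)
        self.no = 2 * nocc
        self.nv = 2 * (nmo - nocc)
        o_sp = np.arange(nocc)
        v_sp = np.arange(nocc, nmo)
        # spin-orbital index -> (spatial index, spin)
        self.occ_spat = np.concatenate([o_sp, o_sp])
        self.occ_spin = np.concatenate([np.zeros(nocc, int), np.ones(nocc, int)])
        self.virt_spat = np.concatenate([v_sp, v_sp])
        self.virt_spin = np.concatenate([np.zeros(nmo - nocc, int),
                                         np.ones(nmo - nocc, int)])
        self.eps_o = fock_diag[self.occ_spat]
        self.eps_v = fock_diag[self.virt_spat]
        g = g_mo

        def anti(p_spat, p_spin, q_spat, q_spin, r_spat, r_spin, s_spat, s_spin):
            """<pq||rs> over index groups given as (spatial, spin) arrays."""
            d_pr = (p_spin[:, None] == r_spin[None, :]).astype(float)
            d_qs = (q_spin[:, None] == s_spin[None, :]).astype(float)
            d_ps = (p_spin[:, None] == s_spin[None, :]).astype(float)
            d_qr = (q_spin[:, None] == r_spin[None, :]).astype(float)
            coul = g[np.ix_(p_spat, r_spat, q_spat, s_spat)] \
                * d_pr[:, :, None, None] * d_qs[None, None, :, :]
            coul = coul.transpose(0, 2, 1, 3)
            exch = g[np.ix_(p_spat, s_spat, q_spat, r_spat)] \
                * d_ps[:, :, None, None] * d_qr[None, None, :, :]
            exch = exch.transpose(0, 2, 3, 1)
            return coul - exch

        O = (self.occ_spat, self.occ_spin)
        V = (self.virt_spat, self.virt_spin)
        self.oovv = anti(*O, *O, *V, *V)
        self.ovov = anti(*O, *V, *O, *V)
        self.oooo = anti(*O, *O, *O, *O)
        self.vvvv = anti(*V, *V, *V, *V)
        self.ooov = anti(*O, *O, *O, *V)
        self.ovvv = anti(*O, *V, *V, *V)


@dataclass
class CISDResult:
    energy: float
    correlation_energy: float
    c0: float
    c1: np.ndarray             # (no, nv) spin-orbital singles
    c2: np.ndarray             # (no, no, nv, nv) antisymmetrized doubles
    rdm1_mo: np.ndarray        # spin-summed spatial MO basis
    converged: bool
    n_iterations: int


def _sigma(blocks: _SpinBlocks, c0, c1, c2):
    """Apply the (HF-shifted) Hamiltonian to a CISD vector.

    Matrix elements are the standard Slater-Condon couplings between the
    reference, singly and doubly excited determinants written with
    antisymmetrized spin-orbital integrals <pq||rs>; canonical orbitals
    make every f_ov term vanish.  The determinant-CI engine is the
    brute-force oracle these contractions are verified against.
    """
    b = blocks
    eo = b.eps_o
    ev = b.eps_v
    # reference block: <0|H_N|D> couplings
    s0 = 0.25 * np.einsum("ijab,ijab->", b.oovv, c2)
    # singles block
    s1 = (ev[None, :] - eo[:, None]) * c1
    # + sum_jb <aj||ib> c_jb  with  <aj||ib> = -<ja||ib> = -ovov[j,a,i,b]
    s1 -= np.einsum("jaib,jb->ia", b.ovov, c1, optimize=True)
    # + 1/2 sum_jbc <aj||bc> c_ijbc  with  <aj||bc> = -ovvv[j,a,b,c]
    s1 -= 0.5 * np.einsum("jabc,ijbc->ia", b.ovvv, c2, optimize=True)
    # - 1/2 sum_jkb <jk||ib> c_jkab
    s1 -= 0.5 * np.einsum("jkib,jkab->ia", b.ooov, c2, optimize=True)
    # doubles block
    D2 = (ev[None, None, :, None] + ev[None, None, None, :]
          - eo[:, None, None, None] - eo[None, :, None, None])
    s2 = b.oovv * c0 + D2 * c2
    s2 += 0.5 * np.tensordot(c2, b.vvvv, axes=([2, 3], [2, 3]))
    s2 += 0.5 * np.tensordot(b.oooo, c2, axes=([2, 3], [0, 1]))
    # ring: P(ij)P(ab) sum_kc <kb||cj> c_ikac ; <kb||cj> = -ovov[k,b,j,c]
    W = -b.ovov.transpose(0, 1, 3, 2)  # W[k,b,c,j]
    t = np.einsum("ikac,kbcj->ijab", c2, W, optimize=True)
    s2 += t - t.transpose(1, 0, 2, 3) - t.transpose(0, 1, 3, 2) \
        + t.transpose(1, 0, 3, 2)
    # + P(ij) sum_c <ab||cj> c_ic ; <ab||cj> = -<jc||ab> = -ovvv[j,c,a,b]
    u = -np.einsum("ic,jcab->ijab", c1, b.ovvv, optimize=True)
    s2 += u - u.transpose(1, 0, 2, 3)
    # - P(ab) sum_k <kb||ij> c_ka ; <kb||ij> = <ij||kb> = ooov[i,j,k,b]
    x = np.einsum("ka,ijkb->ijab", c1, b.ooov, optimize=True)
    s2 -= x - x.transpose(0, 1, 3, 2)
    return float(s0), s1, s2


def _inner(u, v):
    return (u[0] * v[0] + np.sum(u[1] * v[1])
            + 0.25 * np.sum(u[2] * v[2]))


def _axpy(alpha, u, v):
    return (v[0] + alpha * u[0], v[1] + alpha * u[1], v[2] + alpha * u[2])


def _scale(alpha, u):
    return (alpha * u[0], alpha * u[1], alpha * u[2])


def _antisymmetrize(c2):
    c2 = c2 - c2.transpose(1, 0, 2, 3)
    c2 = c2 - c2.transpose(0, 1, 3, 2)
    return 0.25 * (c2 + c2.transpose(1, 0, 3, 2))


def cisd_davidson(g_mo: np.ndarray, fock_diag: np.ndarray, nocc: int,
                  conv_tol: float = 1e-7, max_iter: int = 80,
                  max_space: int = 24) -> tuple[float, tuple, int, bool]:
    """Lowest CISD root; returns (corr_energy, (c0, c1, c2), niter, conv)."""
    blocks = _SpinBlocks(g_mo, fock_diag, nocc)
    no, nv = blocks.no, blocks.nv
    D1 = blocks.eps_v[None, :] - blocks.eps_o[:, None]
    D2 = (blocks.eps_v[None, None, :, None] + blocks.eps_v[None, None, None, :]
          - blocks.eps_o[:, None, None, None] - blocks.eps_o[None, :, None, None])
    # MP2-like start vector
    c2_0 = _antisymmetrize(-blocks.oovv / np.where(np.abs(D2) < 1e-12, 1.0, D2))
    v0 = (1.0, np.zeros((no, nv)), c2_0)
    v0 = _scale(1.0 / np.sqrt(_inner(v0, v0)), v0)
    space = [v0]
    sigmas = []
    theta = 0.0
    conv = False
    it = 0
    for it in range(1, max_iter + 1):
        while len(sigmas) < len(space):
            v = space[len(sigmas)]
            sigmas.append(_sigma(blocks, *v))
        n = len(space)
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                A[i, j] = _inner(space[i], sigmas[j])
        A = 0.5 * (A + A.T)
        evals, evecs = np.linalg.eigh(A)
        theta = evals[0]
        y = evecs[:, 0]
        x = (0.0, np.zeros((no, nv)), np.zeros((no, no, nv, nv)))
        sx = (0.0, np.zeros((no, nv)), np.zeros((no, no, nv, nv)))
        for i in range(n):
            x = _axpy(y[i], space[i], x)
            sx = _axpy(y[i], sigmas[i], sx)
        resid = _axpy(-theta, x, sx)
        rnorm = np.sqrt(_inner(resid, resid))
        if rnorm < conv_tol:
            conv = True
            break
        # preconditioned correction
        d0 = -theta if abs(theta) > 1e-12 else 1.0
        corr = (resid[0] / d0,
                resid[1] / np.where(np.abs(D1 - theta) < 1e-6, 1.0, D1 - theta),
                _antisymmetrize(resid[2] / np.where(np.abs(D2 - theta) < 1e-6,
                                                    1.0, D2 - theta)))
        corr = _scale(-1.0, corr)
        # orthogonalize against the subspace
        for v in space:
            corr = _axpy(-_inner(v, corr), v, corr)
        nrm = np.sqrt(_inner(corr, corr))
        if nrm < 1e-12:
            conv = True
            break
        corr = _scale(1.0 / nrm, corr)
        if len(space) >= max_space:
            space = [_scale(1.0 / np.sqrt(_inner(x, x)), x)]
            sigmas = []
        space.append(corr)
    # final eigenvector
    xn = np.sqrt(_inner(x, x))
    x = _scale(1.0 / xn, x)
    if x[0] < 0:
        x = _scale(-1.0, x)
    return float(theta), x, it, conv


def cisd_rdm1(c0: float, c1: np.ndarray, c2: np.ndarray,
              nocc: int, nmo: int) -> np.ndarray:
    """Spin-summed spatial-MO 1-RDM from normalized CISD amplitudes."""
    no = 2 * nocc
    norm2 = c0 ** 2 + np.sum(c1 * c1) + 0.25 * np.sum(c2 * c2)
    # spin-orbital blocks of <Psi| a_p^+ a_q |Psi>
    g_oo = np.eye(no) * norm2 \
        - np.einsum("ia,ja->ij", c1, c1) \
        - 0.5 * np.einsum("ikab,jkab->ij", c2, c2)
    g_vv = np.einsum("ia,ib->ab", c1, c1) \
        + 0.5 * np.einsum("ijac,ijbc->ab", c2, c2)
    g_ov = c0 * c1 + np.einsum("jb,ijab->ia", c1, c2)
    # fold spin blocks to spatial (alpha block + beta block)
    nv_sp = nmo - nocc
    dm = np.zeros((nmo, nmo))
    for s in range(2):
        o_slice = slice(s * nocc, (s + 1) * nocc)
        v_slice = slice(s * nv_sp, (s + 1) * nv_sp)
        dm[:nocc, :nocc] += g_oo[o_slice, o_slice]
        dm[nocc:, nocc:] += g_vv[v_slice, v_slice]
        dm[:nocc, nocc:] += g_ov[o_slice, v_slice]
    dm[nocc:, :nocc] = dm[:nocc, nocc:].T
    return dm / norm2


def cisd(h_mo: np.ndarray, g_mo: np.ndarray, n_electrons: int,
         e_hf_electronic: float, e_nuc: float = 0.0,
         conv_tol: float = 1e-7) -> CISDResult:
    """Amplitude CISD on canonical RHF orbitals.

    ``h_mo``/``g_mo`` are spatial MO integrals (core Hamiltonian and
    chemists' two-electron integrals); the Fock diagonal is rebuilt
    internally from them.
    """
    nmo = len(h_mo)
    nocc = n_electrons // 2
    if 2 * nocc != n_electrons:
        raise ValueError("closed-shell electron count required")
    # canonical orbital energies from the MO-basis Fock matrix
    occ = np.arange(nocc)
    fock = h_mo + 2.0 * np.einsum("pqii->pq", g_mo[:, :, occ][:, :, :, occ]) \
        - np.einsum("piiq->pq", g_mo[:, occ][:, :, occ])
    fock_diag = np.diag(fock).copy()
    corr, (c0, c1, c2), niter, conv = cisd_davidson(
        g_mo, fock_diag, nocc, conv_tol=conv_tol)
    # normalize
    nrm = np.sqrt(c0 ** 2 + np.sum(c1 * c1) + 0.25 * np.sum(c2 * c2))
    c0, c1, c2 = c0 / nrm, c1 / nrm, c2 / nrm
    dm = cisd_rdm1(c0, c1, c2, nocc, nmo)
    return CISDResult(
        energy=e_hf_electronic + corr + e_nuc,
        correlation_energy=corr,
        c0=c0, c1=c1, c2=c2,
        rdm1_mo=0.5 * (dm + dm.T),
        converged=conv,
        n_iterations=niter,
    )
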