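"""Analytic one- and two-electron integrals over contracted Gaussians.

McMurchie-Davidson scheme: Cartesian Gaussian products are expanded in
Hermite Gaussians (E coefficients); Coulomb-type integrals then reduce to
Hermite Coulomb integrals (R tensors) built on the Boys function, while
plane-wave (Fourier-transform) integrals reduce to closed-form moments of
Hermite Gaussians,

    FT{ Lambda_tuv }(k) = (ik_x)^t (ik_y)^u (ik_z)^v (pi/p)^{3/2}
                          exp(-|k|^2/(4p)) exp(i k.P).

The kernels operate on the packed-shell arrays produced by
:meth:`xcwfit.basis.BasisSet.packed` and return *raw Cartesian* matrices;
``BasisSet.transform`` (or the equivalent congruence for the density
matrix) maps them to the final, possibly spherical, AO basis.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# Boys function
# --------------------------------------------------------------------------


@njit(cache=True)
def boys(mmax: int, T: float) -> np.ndarray:
    """F_m(T) for m = 0..mmax (downward recursion from a series/asymptote)."""
    F = np.zeros(mmax + 1)
    if T < 1e-13:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2 * m + 1)
        return F
    if T > 35.0:
        # asymptotic F_0 then upward recursion (stable at large T)
        F[0] = 0.5 * np.sqrt(np.pi / T)
        expT = np.exp(-T)
        for m in range(mmax):
            F[m + 1] = ((2 * m + 1) * F[m] - expT) / (2.0 * T)
        return F
    # convergent series for F_mmax, then downward recursion
    term = 1.0 / (2 * mmax + 1)
    s = term
    i = 0
    while True:
        term *= 2.0 * T / (2 * mmax + 2 * i + 3)
        s += term
        i += 1
        if term < 1e-17 * s:
            break
    expT = np.exp(-T)
    F[mmax] = s * expT
    for m in range(mmax - 1, -1, -1):
        F[m] = (2.0 * T * F[m + 1] + expT) / (2 * m + 1)
    return F


# --------------------------------------------------------------------------
# Hermite expansion (E) and Hermite Coulomb (R) tables
# --------------------------------------------------------------------------


@njit(cache=True)
def _e_table(la: int, lb: int, PA: float, PB: float, p: float, K: float) -> np.ndarray:
    """E[i, j, t] coefficients for one Cartesian direction; E[0,0,0] = K."""
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = K
    inv2p = 0.5 / p
    for i in range(la):
        for t in range(i + lb + 1):
            E[i + 1, 0, t] += PA * E[i, 0, t] + (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t + 1] += inv2p * E[i, 0, t]
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 1):
                E[i, j + 1, t] += PB * E[i, j, t] + (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t + 1] += inv2p * E[i, j, t]
    return E


@njit(cache=True)
def _r_table(tmax: int, umax: int, vmax: int, p: float,
             X: float, Y: float, Z: float) -> np.ndarray:
    """Hermite Coulomb integrals R_{tuv} (auxiliary order n = 0)."""
    N = tmax + umax + vmax
    T = p * (X * X + Y * Y + Z * Z)
    F = boys(N, T)
    R = np.zeros((N + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(N + 1):
        R[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for t in range(tmax):
        for n in range(N - t):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    val = X * R[n + 1, t, u, v]
                    if t > 0:
                        val += t * R[n + 1, t - 1, u, v]
                    R[n, t + 1, u, v] = val
    for u in range(umax):
        for n in range(N - u):
            for t in range(tmax + 1):
                for v in range(vmax + 1):
                    val = Y * R[n + 1, t, u, v]
                    if u > 0:
                        val += u * R[n + 1, t, u - 1, v]
                    R[n, t, u + 1, v] = val
    for v in range(vmax):
        for n in range(N - v):
            for t in range(tmax + 1):
                for u in range(umax + 1):
                    val = Z * R[n + 1, t, u, v]
                    if v > 0:
                        val += v * R[n + 1, t, u, v - 1]
                    R[n, t, u, v + 1] = val
    return R[0]


@njit(cache=True)
def _cart_comps(l: int) -> np.ndarray:
    nc = (l + 1) * (l + 2) // 2
    out = np.zeros((nc, 3), dtype=np.int64)
    m = 0
    for i in range(l, -1, -1):
        for j in range(l - i, -1, -1):
            out[m, 0] = i
            out[m, 1] = j
            out[m, 2] = l - i - j
            m += 1
    return out


# --------------------------------------------------------------------------
# One-electron integrals
# --------------------------------------------------------------------------


@njit(cache=True)
def overlap_kinetic_cart(shell_l, prim_start, exps, coefs, centers, cart_start):
    nsh = len(shell_l)
    nc_tot = cart_start[nsh]
    S = np.zeros((nc_tot, nc_tot))
    T = np.zeros((nc_tot, nc_tot))
    for s1 in range(nsh):
        la = shell_l[s1]
        ca = _cart_comps(la)
        A = centers[s1]
        for s2 in range(s1, nsh):
            lb = shell_l[s2]
            cb = _cart_comps(lb)
            B = centers[s2]
            AB2 = 0.0
            for d in range(3):
                AB2 += (A[d] - B[d]) ** 2
            sblock = np.zeros((len(ca), len(cb)))
            tblock = np.zeros((len(ca), len(cb)))
            for pa in range(prim_start[s1], prim_start[s1 + 1]):
                a = exps[pa]
                for pb in range(prim_start[s2], prim_start[s2 + 1]):
                    b = exps[pb]
                    p = a + b
                    mu = a * b / p
                    K = np.exp(-mu * AB2)
                    cc = coefs[pa] * coefs[pb]
                    # E tables per direction with room for j+2 (kinetic)
                    Ex = _e_table(la, lb + 2, (b * (B[0] - A[0])) / p,
                                  (a * (A[0] - B[0])) / p, p, K)
                    Ey = _e_table(la, lb + 2, (b * (B[1] - A[1])) / p,
                                  (a * (A[1] - B[1])) / p, p, 1.0)
                    Ez = _e_table(la, lb + 2, (b * (B[2] - A[2])) / p,
                                  (a * (A[2] - B[2])) / p, p, 1.0)
                    fac = (np.pi / p) ** 1.5
                    for ma in range(len(ca)):
                        i1, j1, k1 = ca[ma, 0], ca[ma, 1], ca[ma, 2]
                        for mb in range(len(cb)):
                            i2, j2, k2 = cb[mb, 0], cb[mb, 1], cb[mb, 2]
                            sx = Ex[i1, i2, 0]
                            sy = Ey[j1, j2, 0]
                            sz = Ez[k1, k2, 0]
                            # 1D kinetic pieces
                            tx = -2.0 * b * b * Ex[i1, i2 + 2, 0] \
                                + b * (2 * i2 + 1) * sx
                            if i2 >= 2:
                                tx -= 0.5 * i2 * (i2 - 1) * Ex[i1, i2 - 2, 0]
                            ty = -2.0 * b * b * Ey[j1, j2 + 2, 0] \
                                + b * (2 * j2 + 1) * sy
                            if j2 >= 2:
                                ty -= 0.5 * j2 * (j2 - 1) * Ey[j1, j2 - 2, 0]
                            tz = -2.0 * b * b * Ez[k1, k2 + 2, 0] \
                                + b * (2 * k2 + 1) * sz
                            if k2 >= 2:
                                tz -= 0.5 * k2 * (k2 - 1) * Ez[k1, k2 - 2, 0]
                            sblock[ma, mb] += cc * fac * sx * sy * sz
                            tblock[ma, mb] += cc * fac * (tx * sy * sz
                                                          + sx * ty * sz
                                                          + sx * sy * tz)
            for ma in range(len(ca)):
                for mb in range(len(cb)):
                    ia = cart_start[s1] + ma
                    ib = cart_start[s2] + mb
                    S[ia, ib] = sblock[ma, mb]
                    S[ib, ia] = sblock[ma, mb]
                    T[ia, ib] = tblock[ma, mb]
                    T[ib, ia] = tblock[ma, mb]
    return S, T


@njit(cache=True)
def nuclear_cart(shell_l, prim_start, exps, coefs, centers, cart_start,
                 atom_z, atom_coords):
    nsh = len(shell_l)
    nc_tot = cart_start[nsh]
    V = np.zeros((nc_tot, nc_tot))
    natm = len(atom_z)
    for s1 in range(nsh):
        la = shell_l[s1]
        ca = _cart_comps(la)
        A = centers[s1]
        for s2 in range(s1, nsh):
            lb = shell_l[s2]
            cb = _cart_comps(lb)
            B = centers[s2]
            AB2 = 0.0
            for d in range(3):
                AB2 += (A[d] - B[d]) ** 2
            block = np.zeros((len(ca), len(cb)))
            for pa in range(prim_start[s1], prim_start[s1 + 1]):
                a = exps[pa]
                for pb in range(prim_start[s2], prim_start[s2 + 1]):
                    b = exps[pb]
                    p = a + b
                    mu = a * b / p
                    K = np.exp(-mu * AB2)
                    cc = coefs[pa] * coefs[pb]
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    Ex = _e_table(la, lb, Px - A[0], Px - B[0], p, K)
                    Ey = _e_table(la, lb, Py - A[1], Py - B[1], p, 1.0)
                    Ez = _e_table(la, lb, Pz - A[2], Pz - B[2], p, 1.0)
                    pref = 2.0 * np.pi / p * cc
                    for iat in range(natm):
                        R = _r_table(la + lb, la + lb, la + lb, p,
                                     Px - atom_coords[iat, 0],
                                     Py - atom_coords[iat, 1],
                                     Pz - atom_coords[iat, 2])
                        Z = atom_z[iat]
                        for ma in range(len(ca)):
                            i1, j1, k1 = ca[ma, 0], ca[ma, 1], ca[ma, 2]
                            for mb in range(len(cb)):
                                i2, j2, k2 = cb[mb, 0], cb[mb, 1], cb[mb, 2]
                                acc = 0.0
                                for t in range(i1 + i2 + 1):
                                    et = Ex[i1, i2, t]
                                    if et == 0.0:
                                        continue
                                    for u in range(j1 + j2 + 1):
                                        eu = Ey[j1, j2, u]
                                        if eu == 0.0:
                                            continue
                                        for v in range(k1 + k2 + 1):
                                            ev = Ez[k1, k2, v]
                                            if ev != 0.0:
                                                acc += et * eu * ev * R[t, u, v]
                                block[ma, mb] += -Z * pref * acc
            for ma in range(len(ca)):
                for mb in range(len(cb)):
                    ia = cart_start[s1] + ma
                    ib = cart_start[s2] + mb
                    V[ia, ib] = block[ma, mb]
                    V[ib, ia] = block[ma, mb]
    return V


# --------------------------------------------------------------------------
# Two-electron repulsion integrals
# --------------------------------------------------------------------------


@njit(cache=True)
def _pair_hermite(shell_l, prim_start, exps, coefs, centers, s1, s2):
    """Per-primitive-pair Hermite data for a shell pair.

    Returns (npp, p_arr, P_arr, Etabs) where Etabs is a dense array
    [npp, 3, la+1, lb+1, la+lb+2] of E coefficients (K folded into x).
    """
    la = shell_l[s1]
    lb = shell_l[s2]
    A = centers[s1]
    B = centers[s2]
    AB2 = 0.0
    for d in range(3):
        AB2 += (A[d] - B[d]) ** 2
    na = prim_start[s1 + 1] - prim_start[s1]
    nb = prim_start[s2 + 1] - prim_start[s2]
    npp = na * nb
    p_arr = np.zeros(npp)
    c_arr = np.zeros(npp)
    P_arr = np.zeros((npp, 3))
    E = np.zeros((npp, 3, la + 1, lb + 1, la + lb + 2))
    idx = 0
    for pa in range(prim_start[s1], prim_start[s1 + 1]):
        a = exps[pa]
        for pb in range(prim_start[s2], prim_start[s2 + 1]):
            b = exps[pb]
            p = a + b
            mu = a * b / p
            K = np.exp(-mu * AB2)
            p_arr[idx] = p
            c_arr[idx] = coefs[pa] * coefs[pb]
            for d in range(3):
                P_arr[idx, d] = (a * A[d] + b * B[d]) / p
            E[idx, 0] = _e_table(la, lb, P_arr[idx, 0] - A[0],
                                 P_arr[idx, 0] - B[0], p, K)
            E[idx, 1] = _e_table(la, lb, P_arr[idx, 1] - A[1],
                                 P_arr[idx, 1] - B[1], p, 1.0)
            E[idx, 2] = _e_table(la, lb, P_arr[idx, 2] - A[2],
                                 P_arr[idx, 2] - B[2], p, 1.0)
            idx += 1
    return npp, p_arr, c_arr, P_arr, E


@njit(cache=True)
def eri_cart(shell_l, prim_start, exps, coefs, centers, cart_start):
    """Full raw-Cartesian (mu nu | la si) tensor (chemists' notation)."""
    nsh = len(shell_l)
    nc_tot = cart_start[nsh]
    eri = np.zeros((nc_tot, nc_tot, nc_tot, nc_tot))
    for s1 in range(nsh):
        la = shell_l[s1]
        ca = _cart_comps(la)
        for s2 in range(s1 + 1):
            lb = shell_l[s2]
            cb = _cart_comps(lb)
            np12, p12, c12, P12, E12 = _pair_hermite(
                shell_l, prim_start, exps, coefs, centers, s1, s2)
            for s3 in range(s1 + 1):
                lc = shell_l[s3]
                cc_ = _cart_comps(lc)
                s4max = s2 if s3 == s1 else s3
                for s4 in range(s4max + 1):
                    ld = shell_l[s4]
                    cd = _cart_comps(ld)
                    np34, p34, c34, P34, E34 = _pair_hermite(
                        shell_l, prim_start, exps, coefs, centers, s3, s4)
                    block = np.zeros((len(ca), len(cb), len(cc_), len(cd)))
                    L12 = la + lb
                    L34 = lc + ld
                    for i12 in range(np12):
                        p = p12[i12]
                        for i34 in range(np34):
                            q = p34[i34]
                            alpha = p * q / (p + q)
                            R = _r_table(L12 + L34, L12 + L34, L12 + L34,
                                         alpha,
                                         P12[i12, 0] - P34[i34, 0],
                                         P12[i12, 1] - P34[i34, 1],
                                         P12[i12, 2] - P34[i34, 2])
                            pref = (2.0 * np.pi ** 2.5
                                    / (p * q * np.sqrt(p + q))
                                    * c12[i12] * c34[i34])
                            for ma in range(len(ca)):
                                i1, j1, k1 = ca[ma, 0], ca[ma, 1], ca[ma, 2]
                                for mb in range(len(cb)):
                                    i2, j2, k2 = cb[mb, 0], cb[mb, 1], cb[mb, 2]
                                    for mc in range(len(cc_)):
                                        i3, j3, k3 = cc_[mc, 0], cc_[mc, 1], cc_[mc, 2]
                                        for md in range(len(cd)):
                                            i4, j4, k4 = cd[md, 0], cd[md, 1], cd[md, 2]
                                            acc = 0.0
                                            for t in range(i1 + i2 + 1):
                                                e1 = E12[i12, 0, i1, i2, t]
                                                if e1 == 0.0:
                                                    continue
                                                for u in range(j1 + j2 + 1):
                                                    e2 = e1 * E12[i12, 1, j1, j2, u]
                                                    if e2 == 0.0:
                                                        continue
                                                    for v in range(k1 + k2 + 1):
                                                        e3 = e2 * E12[i12, 2, k1, k2, v]
                                                        if e3 == 0.0:
                                                            continue
                                                        acc2 = 0.0
                                                        for tt in range(i3 + i4 + 1):
                                                            f1 = E34[i34, 0, i3, i4, tt]
                                                            if f1 == 0.0:
                                                                continue
                                                            for uu in range(j3 + j4 + 1):
                                                                f2 = f1 * E34[i34, 1, j3, j4, uu]
                                                                if f2 == 0.0:
                                                                    continue
                                                                for vv in range(k3 + k4 + 1):
                                                                    f3 = f2 * E34[i34, 2, k3, k4, vv]
                                                                    if f3 == 0.0:
                                                                        continue
                                                                    sign = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                    acc2 += sign * f3 * R[t + tt, u + uu, v + vv]
                                                        acc += e3 * acc2
                                            block[ma, mb, mc, md] += pref * acc
                    # scatter block with 8-fold permutational symmetry
                    o1 = cart_start[s1]
                    o2 = cart_start[s2]
                    o3 = cart_start[s3]
                    o4 = cart_start[s4]
                    for ma in range(len(ca)):
                        for mb in range(len(cb)):
                            for mc in range(len(cc_)):
                                for md in range(len(cd)):
                                    v = block[ma, mb, mc, md]
                                    i = o1 + ma
                                    j = o2 + mb
                                    k = o3 + mc
                                    l = o4 + md
                                    eri[i, j, k, l] = v
                                    eri[j, i, k, l] = v
                                    eri[i, j, l, k] = v
                                    eri[j, i, l, k] = v
                                    eri[k, l, i, j] = v
                                    eri[l, k, i, j] = v
                                    eri[k, l, j, i] = v
                                    eri[l, k, j, i] = v
    return eri


# --------------------------------------------------------------------------
# Fourier-transform (plane-wave) integrals
# --------------------------------------------------------------------------


@njit(cache=True, parallel=False)
def ft_blocks_cart(shell_l, prim_start, exps, coefs, centers, cart_start,
                   kvecs):
    """I_k[mu, nu] = int chi_mu chi_nu exp(i k.r) dr  (raw Cartesian AOs).

    ``kvecs`` are the plane-wave vectors in rad/bohr (i.e. 2*pi*B*h already
    converted); output has shape (nk, nc_tot, nc_tot), complex128.
    """
    nsh = len(shell_l)
    nc_tot = cart_start[nsh]
    nk = len(kvecs)
    out = np.zeros((nk, nc_tot, nc_tot), dtype=np.complex128)
    for s1 in range(nsh):
        la = shell_l[s1]
        ca = _cart_comps(la)
        for s2 in range(s1 + 1):
            lb = shell_l[s2]
            cb = _cart_comps(lb)
            np12, p12, c12, P12, E12 = _pair_hermite(
                shell_l, prim_start, exps, coefs, centers, s1, s2)
            o1 = cart_start[s1]
            o2 = cart_start[s2]
            L = la + lb
            for ik in range(nk):
                kx = kvecs[ik, 0]
                ky = kvecs[ik, 1]
                kz = kvecs[ik, 2]
                k2 = kx * kx + ky * ky + kz * kz
                for i12 in range(np12):
                    p = p12[i12]
                    gauss = (np.pi / p) ** 1.5 * np.exp(-k2 / (4.0 * p))
                    phase = np.exp(1j * (kx * P12[i12, 0] + ky * P12[i12, 1]
                                         + kz * P12[i12, 2]))
                    pref = c12[i12] * gauss * phase
                    # powers of (i k_d)
                    powx = np.zeros(L + 1, dtype=np.complex128)
                    powy = np.zeros(L + 1, dtype=np.complex128)
                    powz = np.zeros(L + 1, dtype=np.complex128)
                    powx[0] = 1.0
                    powy[0] = 1.0
                    powz[0] = 1.0
                    for t in range(L):
                        powx[t + 1] = powx[t] * 1j * kx
                        powy[t + 1] = powy[t] * 1j * ky
                        powz[t + 1] = powz[t] * 1j * kz
                    for ma in range(len(ca)):
                        i1, j1, k1 = ca[ma, 0], ca[ma, 1], ca[ma, 2]
                        for mb in range(len(cb)):
                            i2, j2, k2c = cb[mb, 0], cb[mb, 1], cb[mb, 2]
                            sx = 0.0 + 0.0j
                            for t in range(i1 + i2 + 1):
                                sx += E12[i12, 0, i1, i2, t] * powx[t]
                            sy = 0.0 + 0.0j
                            for u in range(j1 + j2 + 1):
                                sy += E12[i12, 1, j1, j2, u] * powy[u]
                            sz = 0.0 + 0.0j
                            for v in range(k1 + k2c + 1):
                                sz += E12[i12, 2, k1, k2c, v] * powz[v]
                            val = pref * sx * sy * sz
                            out[ik, o1 + ma, o2 + mb] += val
                            if s1 != s2 or ma != mb:
                                out[ik, o2 + mb, o1 + ma] += val
    return out


# --------------------------------------------------------------------------
# AO values and derivatives on points
# --------------------------------------------------------------------------


@njit(cache=True)
def ao_values_cart(shell_l, prim_start, exps, coefs, centers, cart_start,
                   points, deriv: int):
    """Raw-Cartesian AO values (and optionally derivatives) at points.

    Returns (vals, grad, hess): vals (npt, nc); grad (npt, 3, nc) if
    deriv >= 1 else size-0; hess (npt, 6, nc) [xx,xy,xz,yy,yz,zz] if
    deriv >= 2 else size-0.
    """
    nsh = len(shell_l)
    nc_tot = cart_start[nsh]
    npt = len(points)
    vals = np.zeros((npt, nc_tot))
    grad = np.zeros((npt, 3, nc_tot)) if deriv >= 1 else np.zeros((0, 3, 0))
    hess = np.zeros((npt, 6, nc_tot)) if deriv >= 2 else np.zeros((0, 6, 0))
    for ipt in range(npt):
        x0 = points[ipt, 0]
        y0 = points[ipt, 1]
        z0 = points[ipt, 2]
        for s in range(nsh):
            l = shell_l[s]
            comps = _cart_comps(l)
            dx = x0 - centers[s, 0]
            dy = y0 - centers[s, 1]
            dz = z0 - centers[s, 2]
            r2 = dx * dx + dy * dy + dz * dz
            for pp in range(prim_start[s], prim_start[s + 1]):
                a = exps[pp]
                g = coefs[pp] * np.exp(-a * r2)
                if g == 0.0:
                    continue
                for m in range(len(comps)):
                    i, j, k = comps[m, 0], comps[m, 1], comps[m, 2]
                    # 1D factors f = u^n, f' and f'' of u^n e^{-a u^2}
                    fx = dx ** i
                    fy = dy ** j
                    fz = dz ** k
                    col = cart_start[s] + m
                    vals[ipt, col] += g * fx * fy * fz
                    if deriv >= 1:
                        dfx = -2.0 * a * dx ** (i + 1)
                        if i > 0:
                            dfx += i * dx ** (i - 1)
                        dfy = -2.0 * a * dy ** (j + 1)
                        if j > 0:
                            dfy += j * dy ** (j - 1)
                        dfz = -2.0 * a * dz ** (k + 1)
                        if k > 0:
                            dfz += k * dz ** (k - 1)
                        grad[ipt, 0, col] += g * dfx * fy * fz
                        grad[ipt, 1, col] += g * fx * dfy * fz
                        grad[ipt, 2, col] += g * fx * fy * dfz
                        if deriv >= 2:
                            d2fx = (4.0 * a * a * dx ** (i + 2)
                                    - 2.0 * a * (2 * i + 1) * dx ** i)
                            if i > 1:
                                d2fx += i * (i - 1) * dx ** (i - 2)
                            d2fy = (4.0 * a * a * dy ** (j + 2)
                                    - 2.0 * a * (2 * j + 1) * dy ** j)
                            if j > 1:
                                d2fy += j * (j - 1) * dy ** (j - 2)
                            d2fz = (4.0 * a * a * dz ** (k + 2)
                                    - 2.0 * a * (2 * k + 1) * dz ** k)
                            if k > 1:
                                d2fz += k * (k - 1) * dz ** (k - 2)
                            hess[ipt, 0, col] += g * d2fx * fy * fz
                            hess[ipt, 1, col] += g * dfx * dfy * fz
                            hess[ipt, 2, col] += g * dfx * fy * dfz
                            hess[ipt, 3, col] += g * fx * d2fy * fz
                            hess[ipt, 4, col] += g * fx * dfy * dfz
                            hess[ipt, 5, col] += g * fx * fy * d2fz
    return vals, grad, hess


# --------------------------------------------------------------------------
# Public wrappers (final AO basis)
# --------------------------------------------------------------------------


def core_hamiltonian(basis):
    """S, T, V in the final AO basis."""
    packed = basis.packed()
    S_c, T_c = overlap_kinetic_cart(*packed)
    mol = basis.molecule
    V_c = nuclear_cart(*packed, mol.atomic_numbers.astype(np.float64),
                       mol.coords)
    return basis.transform(S_c), basis.transform(T_c), basis.transform(V_c)


def electron_repulsion(basis):
    """Full (mu nu | la si) tensor in the final AO basis."""
    packed = basis.packed()
    eri_c = eri_cart(*packed)
    C = basis.cart_to_final
    # 4-index congruence transform, one index at a time
    g = np.tensordot(eri_c, C, axes=([3], [0]))
    g = np.tensordot(g, C, axes=([2], [0]))
    g = np.tensordot(g, C, axes=([1], [0]))
    g = np.tensordot(g, C, axes=([0], [0]))
    # tensordot moved transformed axes to the end; restore order
    return np.ascontiguousarray(g.transpose(3, 2, 1, 0))


def ao_evaluate(basis, points, deriv: int = 0):
    """AO values (and derivatives) at Cartesian points (bohr), final basis."""
    packed = basis.packed()
    pts = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
    vals_c, grad_c, hess_c = ao_values_cart(*packed, pts, deriv)
    C = basis.cart_to_final
    vals = vals_c @ C
    grad = grad_c @ C if deriv >= 1 else None
    hess = hess_c @ C if deriv >= 2 else None
    return vals, grad, hess
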