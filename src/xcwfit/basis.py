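"""Contracted Gaussian basis sets.

A :class:`BasisSet` holds shells of contracted Cartesian Gaussians placed on
the atoms of a molecule, plus the block-diagonal transformation to real
spherical-harmonic (pure) functions.  Angular momenta up to d are supported,
which covers the Pople sets the study uses.

Conventions
-----------
* Cartesian components of a shell are ordered lexicographically
  (d: xx, xy, xz, yy, yz, zz).
* Pure d functions are ordered m = -2, -1, 0, +1, +2
  (xy, yz, 3z^2-r^2, xz, x^2-y^2); s and p shells are identical in both
  representations (p kept as x, y, z).
* Each contracted shell is normalized so that its (l,0,0)-type Cartesian
  component has unit self-overlap; the remaining components carry the usual
  double-factorial ratio, making every Cartesian AO individually normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis_data import get_element_shells
from .molecule import Molecule

_ANG = {"S": 0, "P": 1, "D": 2}


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_pure(l: int) -> int:
    return 2 * l + 1


def cart_components(l: int):
    """Lexicographically ordered (i, j, k) exponent triples with i+j+k = l."""
    out = []
    for i in range(l, -1, -1):
        for j in range(l - i, -1, -1):
            out.append((i, j, l - i - j))
    return out


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of a Cartesian primitive of type (l,0,0)."""
    return (
        (2.0 * alpha / np.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / np.sqrt(_double_factorial(2 * l - 1))
    )


@dataclass
class Shell:
    l: int
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients including primitive norms
    center: np.ndarray  # bohr
    atom_index: int


def _normalize_shell(l: int, exps: np.ndarray, raw_coefs: np.ndarray) -> np.ndarray:
    """Scale contraction coefficients: primitive norms + unit contracted norm."""
    c = raw_coefs * np.array([primitive_norm(a, l) for a in exps])
    # self-overlap of the contracted (l,0,0) Cartesian component
    s = 0.0
    for ca, aa in zip(c, exps):
        for cb, ab in zip(c, exps):
            p = aa + ab
            s += ca * cb * (np.pi / p) ** 1.5 * _double_factorial(2 * l - 1) / (2 * p) ** l
    return c / np.sqrt(s)


# pure-d rows (m = -2..2) in terms of *normalized* Cartesian components
_D_PURE = np.array(
    [
        [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],                       # xy
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],                       # yz
        [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0],                     # 3z^2 - r^2
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],                       # xz
        [np.sqrt(3.0) / 2.0, 0.0, 0.0, -np.sqrt(3.0) / 2.0, 0.0, 0.0],  # x^2-y^2
    ]
)


class BasisSet:
    """A molecule-bound contracted Gaussian basis."""

    def __init__(self, molecule: Molecule, name: str, pure: bool = True):
        self.molecule = molecule
        self.name = name
        self.pure = pure
        self.shells: list[Shell] = []
        for iatm, sym in enumerate(molecule.symbols):
            for ang, exps, coefs in get_element_shells(name, sym):
                exps = np.asarray(exps, dtype=float)
                if ang == "SP":
                    cs, cp = coefs
                    self.shells.append(
                        Shell(0, exps, _normalize_shell(0, exps, np.asarray(cs, float)),
                              molecule.coords[iatm], iatm)
                    )
                    self.shells.append(
                        Shell(1, exps, _normalize_shell(1, exps, np.asarray(cp, float)),
                              molecule.coords[iatm], iatm)
                    )
                else:
                    l = _ANG[ang]
                    self.shells.append(
                        Shell(l, exps, _normalize_shell(l, exps, np.asarray(coefs, float)),
                              molecule.coords[iatm], iatm)
                    )
        self._build_layout()

    # ------------------------------------------------------------------
    def _build_layout(self) -> None:
        self.n_cart_total = sum(n_cart(sh.l) for sh in self.shells)
        self.nbf = sum(
            (n_pure(sh.l) if self.pure else n_cart(sh.l)) for sh in self.shells
        )
        # cart -> final transform, (n_cart_total, nbf)
        T = np.zeros((self.n_cart_total, self.nbf))
        # per-cartesian-AO angular normalization relative to the (l,0,0) member
        scale = np.zeros(self.n_cart_total)
        ic = 0
        ib = 0
        self.cart_offsets = []
        self.ao_offsets = []
        for sh in self.shells:
            self.cart_offsets.append(ic)
            self.ao_offsets.append(ib)
            nc = n_cart(sh.l)
            for m, (i, j, k) in enumerate(cart_components(sh.l)):
                scale[ic + m] = np.sqrt(
                    _double_factorial(2 * sh.l - 1)
                    / (
                        _double_factorial(2 * i - 1)
                        * _double_factorial(2 * j - 1)
                        * _double_factorial(2 * k - 1)
                    )
                )
            if self.pure and sh.l == 2:
                T[ic : ic + 6, ib : ib + 5] = _D_PURE.T
                ib += 5
            else:
                nb = nc
                T[ic : ic + nc, ib : ib + nb] = np.eye(nc)
                ib += nb
            ic += nc
        self.cart_scale = scale
        # fold the per-component normalization into the transform so that
        # M_final = C^T M_cart_raw C for any one-electron matrix
        self.cart_to_final = T * scale[:, None]

    # ------------------------------------------------------------------
    @property
    def ao_labels(self) -> list[str]:
        labels = []
        pure_d = ["d-2", "d-1", "d0", "d+1", "d+2"]
        for sh in self.shells:
            sym = self.molecule.symbols[sh.atom_index]
            if sh.l == 0:
                labels.append(f"{sh.atom_index}{sym} s")
            elif sh.l == 1:
                labels += [f"{sh.atom_index}{sym} p{ax}" for ax in "xyz"]
            elif self.pure:
                labels += [f"{sh.atom_index}{sym} {c}" for c in pure_d]
            else:
                labels += [
                    f"{sh.atom_index}{sym} d{''.join('xyz'[t]*e for t, e in enumerate(ijk))}"
                    for ijk in cart_components(2)
                ]
        return labels

    def packed(self):
        """Flat arrays consumed by the numba integral kernels."""
        nsh = len(self.shells)
        shell_l = np.array([sh.l for sh in self.shells], dtype=np.int64)
        prim_start = np.zeros(nsh + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            prim_start[i + 1] = prim_start[i] + len(sh.exps)
        exps = np.concatenate([sh.exps for sh in self.shells])
        coefs = np.concatenate([sh.coefs for sh in self.shells])
        centers = np.array([sh.center for sh in self.shells])
        cart_start = np.zeros(nsh + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            cart_start[i + 1] = cart_start[i] + n_cart(sh.l)
        return shell_l, prim_start, exps, coefs, centers, cart_start

    def transform(self, m_cart_raw: np.ndarray) -> np.ndarray:
        """Raw-Cartesian one-electron matrix -> final AO basis."""
        C = self.cart_to_final
        return C.T @ m_cart_raw @ C

    def __len__(self) -> int:
        return self.nbf
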