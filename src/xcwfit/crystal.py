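"""Pseudo-crystal model: unit cell, P1 symmetry, reflection sets, hkl files.

The constrained-wavefunction study places an isolated molecule in a large
P1 cell (default cubic, a = 10 angstrom) so that structure factors sample the
molecular charge density without overlap between periodic images.  Only the
identity symmetry operation is supported; the resolution of a reflection is
s = sin(theta)/lambda = |B h| / 2 with B the reciprocal-lattice matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class UnitCell:
    """Unit cell; lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.volume() <= 1e-12:
            raise ValueError("degenerate cell: zero volume")

    def direct_matrix(self) -> np.ndarray:
        """Rows are the direct lattice vectors a, b, c (angstrom)."""
        al, be, ga = np.deg2rad([self.alpha, self.beta, self.gamma])
        va = np.array([self.a, 0.0, 0.0])
        vb = np.array([self.b * np.cos(ga), self.b * np.sin(ga), 0.0])
        cx = np.cos(be)
        cy = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(0.0, 1.0 - cx * cx - cy * cy))
        vc = self.c * np.array([cx, cy, cz])
        return np.array([va, vb, vc])

    def volume(self) -> float:
        al, be, ga = np.deg2rad([self.alpha, self.beta, self.gamma])
        t = (1.0 - np.cos(al) ** 2 - np.cos(be) ** 2 - np.cos(ga) ** 2
             + 2.0 * np.cos(al) * np.cos(be) * np.cos(ga))
        return self.a * self.b * self.c * np.sqrt(max(t, 0.0))

    @classmethod
    def cubic(cls, a: float) -> "UnitCell":
        return cls(a, a, a)


def build_reciprocal_matrix(cell: UnitCell) -> np.ndarray:
    """Reciprocal-lattice matrix B (columns b1, b2, b3; angstrom^-1).

    q = B h for integer Miller triples h; B is the inverse transpose of the
    matrix whose rows are the direct lattice vectors (crystallographic
    convention, no 2*pi factor).
    """
    A = cell.direct_matrix()  # rows are the direct vectors
    return np.linalg.inv(A)   # columns are the reciprocal vectors b_i


def resolution_of(hkl, cell: UnitCell) -> float:
    """s = sin(theta)/lambda = |B h| / 2 in angstrom^-1."""
    B = build_reciprocal_matrix(cell)
    q = B @ np.asarray(hkl, dtype=float)
    return 0.5 * float(np.linalg.norm(q))


@dataclass(frozen=True)
class SpaceGroup:
    """Space-group operations; only P1 (identity) is accepted."""

    operations: tuple = ((np.eye(3), np.zeros(3)),)

    def __post_init__(self):
        if len(self.operations) != 1:
            raise ValueError("only the P1 space group (identity) is supported")
        R, t = self.operations[0]
        if not (np.allclose(R, np.eye(3)) and np.allclose(t, 0.0)):
            raise ValueError("only the identity operation is supported (P1)")

    @property
    def multiplicity(self) -> int:
        return 1


P1 = SpaceGroup()


@dataclass
class Reflection:
    hkl: tuple
    s: float            # resolution sin(theta)/lambda, angstrom^-1
    f_obs: float = np.nan   # amplitude, electrons
    sigma: float = 1.0

    def __post_init__(self):
        if tuple(self.hkl) == (0, 0, 0):
            raise ValueError("(0,0,0) may not appear in a constraint set")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ReflectionSet:
    """An ordered, duplicate-free list of reflections for one cell."""

    cell: UnitCell
    reflections: list
    s_max: float
    friedel_policy: str = "unique-hemisphere"

    def __post_init__(self):
        seen = set()
        for r in self.reflections:
            key = tuple(r.hkl)
            if key in seen:
                raise ValueError(f"duplicate reflection {key}")
            seen.add(key)
        if self.friedel_policy == "unique-hemisphere":
            for key in seen:
                if tuple(-k for k in key) in seen:
                    raise ValueError(
                        f"Friedel mates {key} and {tuple(-k for k in key)} "
                        "coexist under unique-hemisphere policy"
                    )

    def __len__(self) -> int:
        return len(self.reflections)

    def __iter__(self):
        return iter(self.reflections)

    @property
    def hkl_array(self) -> np.ndarray:
        return np.array([r.hkl for r in self.reflections], dtype=np.int64)

    @property
    def s_array(self) -> np.ndarray:
        return np.array([r.s for r in self.reflections])

    @property
    def f_obs(self) -> np.ndarray:
        return np.array([r.f_obs for r in self.reflections])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([r.sigma for r in self.reflections])

    def with_amplitudes(self, amplitudes: np.ndarray, sigma: float = 1.0
                        ) -> "ReflectionSet":
        if len(amplitudes) != len(self.reflections):
            raise ValueError("amplitude list length mismatch")
        refls = [
            Reflection(r.hkl, r.s, float(f), sigma)
            for r, f in zip(self.reflections, amplitudes)
        ]
        return ReflectionSet(self.cell, refls, self.s_max, self.friedel_policy)

    def truncated(self, s_max: float) -> "ReflectionSet":
        """Sub-set with resolution cutoff s_max (keeps amplitudes)."""
        refls = [r for r in self.reflections if r.s <= s_max + 1e-12]
        return ReflectionSet(self.cell, refls, s_max, self.friedel_policy)


def _hemisphere_key(h: tuple) -> bool:
    """True if h is the lexicographically positive member of the +-h pair."""
    for x in h:
        if x > 0:
            return True
        if x < 0:
            return False
    return False  # origin


def generate_reflection_set(
    cell: UnitCell,
    s_max: float,
    friedel_policy: str = "unique-hemisphere",
    space_group: SpaceGroup = P1,
) -> ReflectionSet:
    """All integer Miller triples (origin excluded) with s <= s_max.

    Deterministic lexicographic ordering; under the unique-hemisphere policy
    only the lexicographically positive member of each Friedel pair is kept
    (the underlying density is real, so |F(h)| = |F(-h)|).
    """
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    if friedel_policy not in ("unique-hemisphere", "full-sphere"):
        raise ValueError(f"unknown friedel policy {friedel_policy!r}")
    B = build_reciprocal_matrix(cell)
    # conservative index bounds: |h_i| <= 2 s_max / min singular value of B
    smin = np.linalg.svd(B, compute_uv=False)[-1]
    hmax = int(np.ceil(2.0 * s_max / smin)) + 1
    rng = np.arange(-hmax, hmax + 1)
    H = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    q = H @ B.T
    s = 0.5 * np.linalg.norm(q, axis=1)
    mask = (s <= s_max + 1e-12) & ~np.all(H == 0, axis=1)
    H = H[mask]
    s = s[mask]
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0]))
    refls = []
    for idx in order:
        h = tuple(int(x) for x in H[idx])
        if friedel_policy == "unique-hemisphere" and not _hemisphere_key(h):
            continue
        refls.append(Reflection(h, float(s[idx])))
    return ReflectionSet(cell, refls, s_max, friedel_policy)


# --------------------------------------------------------------------------
# hkl text serialization: columns `h k l F sigma`, '#' comments
# --------------------------------------------------------------------------


def write_hkl(rset: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# h k l F sigma\n")
        c = rset.cell
        fh.write(f"# cell {c.a:.6f} {c.b:.6f} {c.c:.6f} "
                 f"{c.alpha:.4f} {c.beta:.4f} {c.gamma:.4f}\n")
        fh.write(f"# s_max {rset.s_max:.6f}  friedel {rset.friedel_policy}\n")
        for r in rset.reflections:
            h, k, l = r.hkl
            fh.write(f"{h:5d} {k:5d} {l:5d} {r.f_obs:18.8e} {r.sigma:12.6g}\n")


def read_hkl(path, cell: UnitCell | None = None,
             friedel_policy: str = "unique-hemisphere") -> ReflectionSet:
    """Read a whitespace-separated `h k l F sigma` file.

    A `# cell` comment written by :func:`write_hkl` restores the cell; an
    explicit ``cell`` argument overrides it.
    """
    refls = []
    file_cell = cell
    s_max_meta = None
    policy = friedel_policy
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                parts = stripped[1:].split()
                if parts[:1] == ["cell"] and cell is None:
                    vals = [float(x) for x in parts[1:7]]
                    file_cell = UnitCell(*vals)
                if parts[:1] == ["s_max"]:
                    s_max_meta = float(parts[1])
                    if len(parts) >= 4 and parts[2] == "friedel":
                        policy = parts[3]
                continue
            parts = stripped.split()
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                f, sig = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed line {lineno}: {line!r}") from exc
            if (h, k, l) == (0, 0, 0):
                raise ValueError(
                    f"{path}: line {lineno}: (0,0,0) is not an allowed "
                    "constraint reflection")
            if sig <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: sigma must be positive")
            refls.append(((h, k, l), f, sig))
    if file_cell is None:
        raise ValueError("no cell metadata in file and none provided")
    out = []
    for hkl, f, sig in refls:
        out.append(Reflection(hkl, resolution_of(hkl, file_cell), f, sig))
    s_max = s_max_meta if s_max_meta is not None else (
        max((r.s for r in out), default=0.0))
    return ReflectionSet(file_cell, out, s_max, policy)
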