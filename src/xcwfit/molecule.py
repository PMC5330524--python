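"""Molecular geometries: in-memory container and XYZ serialization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ANGSTROM_PER_BOHR, ATOMIC_NUMBERS, BOHR_PER_ANGSTROM, ELEMENTS


@dataclass
class Molecule:
    """A molecule: atomic numbers, Cartesian coordinates in bohr, charge, spin.

    Only closed-shell (singlet, even electron count) species are supported,
    which covers every system the constrained-wavefunction fit targets.
    """

    atomic_numbers: np.ndarray
    coords: np.ndarray  # (natm, 3), bohr
    charge: int = 0
    multiplicity: int = 1
    comment: str = ""

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if self.multiplicity != 1:
            raise ValueError("only singlet (closed-shell) molecules are supported")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count {self.n_electrons}: closed shell required"
            )

    @property
    def natm(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def symbols(self) -> list[str]:
        return [ELEMENTS[z] for z in self.atomic_numbers]

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.natm):
            for j in range(i + 1, self.natm):
                r = np.linalg.norm(self.coords[i] - self.coords[j])
                e += self.atomic_numbers[i] * self.atomic_numbers[j] / r
        return e

    def translated(self, shift_bohr: np.ndarray) -> "Molecule":
        return Molecule(
            self.atomic_numbers.copy(),
            self.coords + np.asarray(shift_bohr, dtype=float),
            self.charge,
            self.multiplicity,
            self.comment,
        )

    def centered_in_cell(self, cell_edge_angstrom: float) -> "Molecule":
        """Place the geometric center at the center of a cubic cell."""
        center = self.coords.mean(axis=0)
        target = np.full(3, cell_edge_angstrom / 2.0 * BOHR_PER_ANGSTROM)
        return self.translated(target - center)

    def to_xyz(self) -> str:
        lines = [str(self.natm), self.comment.replace("\n", " ")]
        for sym, xyz in zip(self.symbols, self.coords):
            x, y, z = xyz * ANGSTROM_PER_BOHR
            lines.append(f"{sym:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
        return "\n".join(lines) + "\n"


def write_xyz(mol: Molecule, path) -> None:
    with open(path, "w") as fh:
        fh.write(mol.to_xyz())


def read_xyz(path, charge: int = 0) -> Molecule:
    """Read an XYZ file (coordinates in angstrom)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    natm = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    zs, xyz = [], []
    for ln in lines[2 : 2 + natm]:
        parts = ln.split()
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element symbol {parts[0]!r}")
        zs.append(ATOMIC_NUMBERS[sym])
        xyz.append([float(p) for p in parts[1:4]])
    coords = np.array(xyz) * BOHR_PER_ANGSTROM
    return Molecule(np.array(zs), coords, charge=charge, comment=comment)
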