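"""Shared fixtures: small electronic-structure contexts reused across tests.

Everything is generated at test time; the heavy (production-basis) contexts
live in test_acceptance.py with module scope.
"""

import numpy as np
import pytest

from xcwfit import ElectronicStructure, Molecule, UnitCell
from xcwfit.constants import BOHR_PER_ANGSTROM


@pytest.fixture(scope="session")
def h2_sto3g():
    mol = Molecule([1, 1], [[0, 0, 0], [0, 0, 1.4]])
    return ElectronicStructure(mol, "sto-3g")


@pytest.fixture(scope="session")
def h2_631g():
    mol = Molecule([1, 1], [[0, 0, -0.7], [0, 0, 0.7]])
    return ElectronicStructure(mol, "6-31g")


@pytest.fixture(scope="session")
def water_sto3g():
    r = 0.9572 * BOHR_PER_ANGSTROM
    ang = np.deg2rad(104.52)
    mol = Molecule(
        [8, 1, 1],
        [[0, 0, 0], [r, 0, 0], [r * np.cos(ang), r * np.sin(ang), 0]],
    )
    return ElectronicStructure(mol, "sto-3g")


@pytest.fixture(scope="session")
def cell10():
    return UnitCell.cubic(10.0)
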