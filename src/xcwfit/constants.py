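"""Physical constants and unit conversions.

All internal quantum-chemical quantities are in Hartree atomic units
(lengths in bohr, energies in hartree).  Crystallographic interfaces
(unit cells, resolutions) use angstroms and inverse angstroms.
"""

#: 1 angstrom in bohr (CODATA, truncated; the value used at every interface).
BOHR_PER_ANGSTROM = 1.8897261246

ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: Element symbols indexed by atomic number (up to Ar; the systems treated
#: here are first- and second-row molecules).
ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBERS = {sym: z for z, sym in enumerate(ELEMENTS)}
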