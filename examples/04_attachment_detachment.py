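"""Attachment/detachment picture of the correlation-driven reorganization.

The difference between a correlated (or constrained) density and RHF is
split into a detachment part (density removed, mostly from the bond) and
an attachment part (density gained, mostly near the nuclei).  Their common
trace p counts the promoted electrons; the constrained fit always
reorganizes less than the correlated benchmark itself.
"""

import numpy as np

from xcwfit import (ElectronicStructure, UnitCell, XCRHFSolver,
                    attach_detach_decomposition, correlated_density,
                    fixture_geometry, generate_reflection_set,
                    make_reference_amplitudes, rhf_density)

basis = "6-311++g(2d,2p)"
mol = fixture_geometry("H2").centered_in_cell(10.0)
es = ElectronicStructure(mol, basis)
hf = rhf_density(mol, basis, es)
fci = correlated_density(mol, basis, "FCI", es)

obs = make_reference_amplitudes(
    fci, generate_reflection_set(UnitCell.cubic(10.0), 0.7))
xc = XCRHFSolver(mol, es.basis, obs).scan([0.0, 5.0, 10.0])[-1]

ad_fci = attach_detach_decomposition(hf.P, fci.P, es.S)
ad_xc = attach_detach_decomposition(hf.P, xc.density_matrix, es.S)
print(f"promoted electrons p (FCI vs RHF):    {ad_fci.promoted_electrons:.5f}")
print(f"promoted electrons p (XC-RHF vs RHF): {ad_xc.promoted_electrons:.5f}")
print("p(XC-RHF) < p(FCI): the constrained determinant reproduces only "
      "part of the correlation-driven charge reorganization.")
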