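"""Quantify how much correlation the constrained wavefunction recovers.

Five indicators compare the constrained density with the correlated
benchmark: TI at the bond critical point (100 = pure RHF, 0 = full
recovery), RSR, the Carbo distance, RMSD and MAD on a real-space grid.
"""

import numpy as np

from xcwfit import (ElectronicStructure, GridSpec, UnitCell, XCRHFSolver,
                    carbo_distance, correlated_density, density_on_grid,
                    find_bcp, fixture_geometry, generate_reflection_set,
                    make_reference_amplitudes, rhf_density, rmsd_mad, rsr,
                    topological_index)

basis = "6-311++g(2d,2p)"
mol = fixture_geometry("H2").centered_in_cell(10.0)
es = ElectronicStructure(mol, basis)
hf = rhf_density(mol, basis, es)
fci = correlated_density(mol, basis, "FCI", es)

refl = generate_reflection_set(UnitCell.cubic(10.0), 0.7)
obs = make_reference_amplitudes(fci, refl)
solver = XCRHFSolver(mol, es.basis, obs)
xc = solver.scan([0.0, 2.5, 5.0, 7.5, 10.0])[-1]

rho_rhf = find_bcp(hf.P, es.basis, 0, 1).rho
rho_fci = find_bcp(fci.P, es.basis, 0, 1).rho
rho_xc = find_bcp(xc.density_matrix, es.basis, 0, 1).rho
ti = topological_index(rho_xc, rho_rhf, rho_fci)
print(f"rho at the H-H bond critical point (e/bohr^3):")
print(f"  RHF {rho_rhf:.5f}   FCI {rho_fci:.5f}   XC-RHF {rho_xc:.5f}")
print(f"TI(XC-RHF, lambda_J = 10, s_max = 0.7) = {ti:.1f}  "
      "(between 0 and 100: partial recovery)")

grid = GridSpec.around(mol, spacing=0.15)
f_fci = density_on_grid(fci.P, es.basis, grid)
for label, P in [("RHF", hf.P), ("XC-RHF", xc.density_matrix)]:
    f = density_on_grid(P, es.basis, grid)
    r, m = rmsd_mad(f, f_fci)
    print(f"{label:7s} vs FCI:  RSR = {rsr(f, f_fci):.5f}  "
          f"d_Carbo = {carbo_distance(f, f_fci):.5f}  "
          f"RMSD = {r:.2e}  MAD = {m:.2e}")
print("Every indicator shrinks from RHF to XC-RHF: the constraint has "
      "pulled the single determinant toward the correlated density.")
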