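"""Build a pseudo-crystal reflection set and compute structure factors.

An isolated H2 molecule is placed at the center of a 10 angstrom cubic P1
cell; the analytic Fourier transform of its RHF density gives the
theoretical structure-factor amplitudes that later serve as "observed"
data for the constrained fit.
"""

import numpy as np

from xcwfit import (ElectronicStructure, UnitCell, fixture_geometry,
                    generate_reflection_set, make_reference_amplitudes,
                    rhf_density, write_hkl)

cell = UnitCell.cubic(10.0)
refl = generate_reflection_set(cell, s_max=0.5)
print(f"reflections with sin(theta)/lambda <= 0.5 A^-1 "
      f"(Friedel-unique hemisphere): {len(refl)}")

mol = fixture_geometry("H2").centered_in_cell(10.0)
es = ElectronicStructure(mol, "6-311++g(2d,2p)")
hf = rhf_density(mol, "6-311++g(2d,2p)", es)
obs = make_reference_amplitudes(hf, refl)

print(f"RHF energy: {hf.energy:.6f} hartree")
print("lowest-resolution amplitudes (electrons):")
for r in obs.reflections[:5]:
    print(f"  h = {r.hkl}, s = {r.s:.3f} A^-1, |F| = {r.f_obs:.5f}")
print("The amplitudes decay with resolution; |F| at s -> 0 approaches the "
      "electron count (2).")

write_hkl(obs, "h2_rhf.hkl")
print("wrote h2_rhf.hkl")
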