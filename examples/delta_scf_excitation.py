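"""Delta-SCF excited state of XY2 via the Ziegler sum rule.

Two occupation-constrained unrestricted SCC calculations -- the triplet
(parallel spins in HOMO and LUMO) and the mixed determinant (antiparallel) --
give E_s = 2 E_m - E_t for the singlet. The transition dipole between the
separately optimized ground and excited determinants comes from the
corresponding orbital transformation (COT).
"""

import numpy as np

from minidftb import build_suite, cot_transition_dipole, delta_dftb
from minidftb.units import EV_PER_HARTREE

suite = build_suite()
geom = suite.geometry("XY2")

res = delta_dftb(geom, suite.params, "dftb2")
e0 = res["ground"].e_total
print(f"ground   E   = {e0:.8f} Ha")
print(f"triplet  E_t = {res['E_t']:.8f} Ha  "
      f"({(res['E_t'] - e0) * EV_PER_HARTREE:.3f} eV)")
print(f"mixed    E_m = {res['E_m']:.8f} Ha")
print(f"singlet  E_s = 2 E_m - E_t = {res['E_s']:.8f} Ha  "
      f"({(res['E_s'] - e0) * EV_PER_HARTREE:.3f} eV)")

gs = res["ground"]
mixed = res["mixed"]
c_g = gs.mo_coefficients[:, :4]
c_e = mixed.c_up[:, np.where(mixed.occ_up > 0.5)[0]]
tdm = cot_transition_dipole(c_g, c_e, gs.overlap, geom, gs.basis)
print(f"COT transition dipole (e*bohr): "
      f"[{tdm[0]:+.4f}, {tdm[1]:+.4f}, {tdm[2]:+.4f}]")

# The singlet sits above the triplet by twice the exchange-like splitting of
# the mixed determinant; a near-zero TDM flags a symmetry-forbidden
# HOMO -> LUMO promotion.
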