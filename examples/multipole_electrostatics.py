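"""Monopole vs multipolar (mDFTB) electrostatics on the bent XY2 molecule.

With the multipole extension the charge fluctuations carry atomic dipoles
and traceless quadrupoles that interact through Taylor derivatives of the
gamma kernel; the on-site dipole of the central atom captures its lone-pair
anisotropy that a pure monopole model misses.
"""

import numpy as np

from minidftb import build_suite, scc_loop
from minidftb.scc import SCCOptions

suite = build_suite()
geom = suite.geometry("XY2")

plain = scc_loop(geom, suite.params, "dftb2")
multi = scc_loop(geom, suite.params, "dftb2", SCCOptions(multipole=True))

print(f"DFTB2  (monopole):  E = {plain.e_total:.8f} Ha")
print(f"mDFTB2 (multipole): E = {multi.e_total:.8f} Ha")
print(f"multipole correction: {multi.e_total - plain.e_total:+.6f} Ha")
print()
for a, sym in enumerate(geom.symbols):
    d = multi.moments.dd[a]
    q = multi.moments.dQ[a]
    print(f"atom {a + 1} ({sym}): |dipole| = {np.linalg.norm(d):.4f} a.u., "
          f"|quadrupole| = {np.linalg.norm(q):.4f} a.u.")

# Only the central Y atom (the one with a p shell) develops on-site moments;
# the s-only X atoms contribute monopoles alone, so their rows are zero.
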