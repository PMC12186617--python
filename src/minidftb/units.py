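"""Unit conversion constants (CODATA 2018).

All internal math is done in hartree / bohr; angstrom and eV appear only at
I/O boundaries.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
EV_PER_HARTREE = 27.211386245988
KCALMOL_PER_HARTREE = 627.5094740631


def hartree_to_ev(e: float) -> float:
    return e * EV_PER_HARTREE


def hartree_to_kcalmol(e: float) -> float:
    return e * KCALMOL_PER_HARTREE
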