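"""Linear-response TD-DFTB spectrum of the closed-shell XY(-) diatomic.

Transition Mulliken charges compress the coupling matrix; the hermitian RPA
problem is solved in its symmetric reduced form and the Tamm-Dancoff
approximation simply diagonalizes the A block. Triplet states couple
through on-site spin constants instead of the Coulomb kernel, so they fall
below their singlet partners.
"""

from minidftb import build_suite, excitation_spectrum
from minidftb.units import EV_PER_HARTREE

suite = build_suite()
geom = suite.geometry("XY")

for channel in ("singlet", "triplet"):
    for method in ("rpa", "tda"):
        _, exc = excitation_spectrum(geom, suite.params, "dftb2",
                                     n_states=4, method=method,
                                     channel=channel)
        line = ", ".join(
            f"{om * EV_PER_HARTREE:.3f} eV (f={f:.3f})"
            for om, f in zip(exc.omegas, exc.oscillator_strengths)
        )
        print(f"{channel:7s} {method.upper():3s}: {line}")

# The two degenerate lowest singlets are the dark pi -> sigma* pair (f = 0,
# perpendicular to the transition dipole axis); the bright state is the
# sigma -> sigma* transition along the bond.
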