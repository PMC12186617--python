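"""Ground-state SCC energies of the bent XY2 molecule at all three model levels.

DFTB1 is a single diagonalization; DFTB2 iterates Mulliken charges through
the gamma kernel; DFTB3 adds the third-order correction driven by the
Hubbard derivative. The breakdown shows how little the repulsive pair term
contributes near equilibrium and how the second- and third-order
electrostatics partially cancel for this polar molecule.
"""

from minidftb import build_suite, scc_loop

suite = build_suite()
geom = suite.geometry("XY2")

for model in ("dftb1", "dftb2", "dftb3"):
    state = scc_loop(geom, suite.params, model)
    t = state.energy_terms
    print(f"{model}:  E_total = {t['E_total']:.8f} Ha  "
          f"(band {t['E_DFTB1']:.6f}, rep {t['E_rep']:.6f}, "
          f"2nd {t['E_2nd']:.6f}, 3rd {t['E_3rd']:.6f})  "
          f"iterations: {state.n_iterations}")
    charges = ", ".join(f"{s}:{-q:+.3f}" for s, q in
                        zip(geom.symbols, state.dq))
    print(f"         partial charges (e): {charges}")

# The central Y atom pulls electron density from the two X atoms; DFTB3
# re-softens that transfer because Y's negative Hubbard derivative makes
# the anionic site softer than second order assumes.
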