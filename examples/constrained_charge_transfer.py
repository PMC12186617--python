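"""Diabatic charge-transfer profile via Mulliken-population constraints.

A Lagrange multiplier forces a chosen number of electrons onto the X atom of
the XY(-) diatomic; the inner SCC stays variational while an outer Newton
iteration drives the population to its target. The internal energy as a
function of transferred charge is convex with its minimum at the
unconstrained ground state.
"""

from minidftb import ConstraintSpec, build_suite, constraint_value, scc_loop, solve_constrained
from minidftb.scc import SCCOptions

suite = build_suite()
geom = suite.geometry("XY")
params = suite.params

free = scc_loop(geom, params, "dftb2")
c0 = constraint_value(free, [0], params)
print(f"unconstrained population on X: {c0:.4f} e, E = {free.e_total:.8f} Ha\n")
print("transfer/e   population   lambda*      E_internal/Ha   cost/Ha")
for shift in (-0.4, -0.2, 0.0, 0.2, 0.4):
    spec = ConstraintSpec(groups=[[0]], targets=[c0 + shift])
    state, info = solve_constrained(geom, params, "dftb2", spec,
                                    SCCOptions(tolerance=1e-11))
    e_int = state.energy_terms["E_total"] - state.energy_terms["E_constraint"]
    print(f"  {shift:+.2f}      {c0 + shift:8.4f}   {info['lambdas'][0]:+9.5f}"
          f"   {e_int:.8f}   {e_int - free.e_total:+.6f}")

# lambda* is the potential (hartree per electron) needed to hold the charge
# in place -- the slope of the diabatic energy profile at that transfer.
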