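# minidftb

A compact, fully self-contained self-consistent-charge tight-binding engine
for molecular systems. It is aimed at method developers and teachers who want
the *entire* machinery of an SCC-DFTB code — parameter-file handling,
Hamiltonian assembly, the charge self-consistency loop, and the excited-state
and environment extensions — in readable Python, testable end to end without
downloading any parameter sets.

## What it implements

**Ground state.** The tight-binding total energy expanded to first, second
and third order in density fluctuations around a superposition of atomic
densities:

```
E(DFTB3) = Σ_i n_i ⟨ψ_i|H⁰|ψ_i⟩ + ½ Σ_AB V_AB^rep
         + ½ Σ_AB Δq_A γ_AB Δq_B + ⅓ Σ_AB Δq_A² Δq_B Γ_AB
```

with Mulliken charge fluctuations Δq_A, the analytic Coulomb kernel γ_AB of
two exponential spherical densities (on-site limit γ_AA(0) = U_A, the
chemical hardness), its charge derivative Γ_AB = (∂γ/∂U_A)·U_A^d, and the
empirically damped γʰ variant for hydrogen-class pairs. H⁰ and S come from
classic Slater–Koster `.skf` tables rotated into the molecular frame.

**Multipolar electrostatics (mDFTB).** Charge fluctuations additionally
carry atomic dipoles Δ**d**_A and traceless quadrupoles Δ**Q**_A in an
on-site approximation; they interact through the Taylor derivatives
f_AB^(mn) = (1/m!n!) ∂^m∂'^n γ(**r**,**r**′) evaluated at the atomic sites,
all derivatives analytic.

**Constrained ground states.** F[P,λ] = E[P] + Σ_i λ_i (C_i[P] − C_i⁰) with
Mulliken-population constraint functionals; maximal in λ, minimal in P.

**Implicit solvent.** Generalized Born / ALPB:
δG_diel = f(ε) Σ_A q_A X_A with f(ε) = −½(ε−1)/(ε+α), α = 0.571214, Still or
P16 interaction kernels and GB^OBC II Born radii, coupled into the SCC shift.

**Excited states.** Linear-response TD-DFTB (full RPA in the symmetric
reduced form, and the Tamm–Dancoff approximation) with Mulliken transition
charges q_A^{ia}; and ΔSCF with the Ziegler sum rule E_s = 2E_m − E_t plus
corresponding-orbital-transformation transition dipoles.

**Synthetic parameters.** A deterministic two-element parameter set (`X`:
one s electron, hydrogen-class; `Y`: six s+p electrons) generated from
closed-form Slater-orbital integrals and an extended-Hückel rule, written
and re-read as ordinary `.skf` files — so every code path above runs out of
the box.

## Worked example

```python
from minidftb import build_suite, scc_loop

suite = build_suite()               # geometries + synthetic parameters
state = scc_loop(suite.geometry("XY2"), suite.params, "dftb3")
print(state.energy_terms)
```

prints (hartree)

```
{'E_DFTB1': -2.96855..., 'E_rep': 0.00104..., 'E_2nd': 0.00591...,
 'E_3rd': -0.00565..., 'E_solv': 0.0, 'E_constraint': 0.0,
 'E_total': -2.96723...}
```

— the band energy of the reference Hamiltonian, the short-range pair
repulsion, and the second/third-order charge-fluctuation corrections, which
partially cancel for this polar molecule: third order re-softens the anionic
site (Y carries −0.66 e at DFTB3 vs −0.53 e at DFTB2).

The `examples/` directory holds one short script per capability
(ground-state models, multipoles, constrained charge transfer, solvation,
TD spectra, ΔSCF); each prints the numbers it computes and a line on what
they mean. A thin CLI wraps the same calls:

```bash
minidftb energy  molecule.xyz --params synthetic --model dftb3
minidftb excite  molecule.gen --params ./my_params --nstates 5 --tda
minidftb delta   molecule.xyz --params synthetic
```

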