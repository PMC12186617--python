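# Methods

This note documents the models implemented in `minidftb`, the conventions
and numerical choices behind them, what the synthetic parameter set does and
does not emulate, and the package's known limitations.

## Energy models

The electronic structure is a minimal-basis tight-binding expansion of the
Kohn–Sham energy in density fluctuations around superposed atomic densities.

**DFTB1.** `E = Σ_i n_i c_i†H⁰c_i + ½ Σ_AB V_AB^rep`. The reference
Hamiltonian H⁰ and overlap S are assembled from two-center bond integrals
tabulated on a radial grid (classic `.skf` format) and rotated into the
molecular frame with direction cosines. Diagonal blocks of H⁰ are the atomic
on-site energies; S has unit diagonal blocks. One diagonalization of the
generalized eigenproblem `H c = ε S c`; no charge self-consistency.

**DFTB2.** Adds `E₂ = ½ Σ_AB Δq_A γ_AB Δq_B`, where Δq_A is the Mulliken
population fluctuation `Σ_{μ∈A}(PS)_{μμ} − q_A⁰` and γ_AB is the Coulomb
integral of two spherical exponential densities with decay constants
τ_A = (16/5)·U_A, so that γ_AA(0) = U_A (the chemical hardness) and
γ_AB → 1/R at large separation. The SCC Hamiltonian is derived
variationally: `H = H⁰ + ½(WS + SW)` with the block-diagonal on-site
potential W_A = (∂E/∂Δq_A)·I, which reduces to the familiar
`½ S_{μν}(V_A + V_B)` shift.

**DFTB3.** Adds `E₃ = ⅓ Σ_AB Δq_A² Δq_B Γ_AB` with
Γ_AB = (∂γ_AB/∂U_A)·U_A^d (the Hubbard derivative U^d = dU/dq models the
charge dependence of the hardness; Γ_AA = U_A^d as the total derivative of
the on-site limit). The third-order shift follows by differentiating E₃:
`V_A^(3) = ⅔ Δq_A (ΓΔq)_A + ⅓ (Γᵀ Δq²)_A`. Setting all U^d = 0 collapses
DFTB3 onto DFTB2 exactly (tested to 1e−12).

**γʰ damping.** For pairs involving a hydrogen-class element the
short-range part of γ is damped: `γʰ = 1/R − S(R)·exp(−((U_A+U_B)/2)^ζ R²)`,
ζ = 4.0 by default (config-exposed). The trigger is the per-element
`hydrogen_class` flag. Γ for damped pairs includes the U-dependence of the
damping exponent (see *Numerics*).

**Spin polarization** appears in two places only: the colinear
occupation-constrained ΔSCF determinants (energy term
`½ Σ_A W_A m_A²` with atomic magnetizations m_A and spin constants W_A,
per-spin shift ±W_A m_A) and the triplet channel of linear response. The
ground-state SCC loop itself is closed-shell restricted.

## Multipolar electrostatics (mDFTB)

In multipole mode the fluctuation on each atom carries, besides Δq_A, an
atomic dipole and a traceless quadrupole computed in the on-site
approximation from the Mulliken-symmetrized on-site density
ρ^A = ½(PS + SP)|_A:

* `Δd_A = s_d·D_A·(ρ_{s,p} + ρ_{p,s})` — the s–p coherence times the
  one-center dipole integral D_A = ⟨s|r|p⟩;
* `ΔQ_A = s_q·Q_A·(ρ_pp − I·tr ρ_pp/3)` — the traceless p-block times the
  one-center quadrupole integral Q_A = (3/5)⟨r²⟩_p.

s_d and s_q are the empirical scaling factors (default 1; they are
parameter-set specific fitted values supplied through the sidecar, never
hard-coded). Setting s_d = s_q = 0 reduces the model to plain DFTB2 exactly.

The interaction kernels are the Taylor derivatives of γ at the atomic
sites, `f^(mn) = (−1)^n/(m!n!) ∇^(m+n) γ(R_A−R_B)`, assembled from analytic
radial derivatives via the standard radial-tensor identities (∇∇f =
(f″−f′/R)n̂n̂ + (f′/R)δ, and the rank-3/rank-4 generalizations). On-site
(A = B) kernels come from the even small-R expansion of γ
(γ = c₀ + c₂R² + c₄R⁴ + …): f⁰⁰ = c₀, f¹¹ = −2c₂δ, f²² = 2c₄(δδ three-fold
sum); odd orders vanish by parity. The γʰ-damped kernel coincides with γ at
R = 0 but is not smooth there (the Gaussian times 1/R generates an odd
term), so the on-site kernels are defined from the *undamped* expansion;
for A ≠ B the damping is Taylor-expanded like everything else, i.e. it
applies to all orders uniformly.

The multipole back-coupling into H is obtained by differentiating the
energy with respect to P through the moment definitions; it lands in the
same `½(WS+SW)` construction with off-diagonal on-site W entries
(s–p entries carry s_d·D_A·v_d, p–p entries s_q·Q_A·v_Q). This derivative
is validated against finite differences of the energy with respect to
individual density-matrix entries.

mDFTB3 adds the monopole third-order term of DFTB3 unchanged.

## Constrained ground states

`F[P,λ] = E[P] + Σ_i λ_i (C_i[P] − C_i⁰)` with C_i the summed Mulliken
populations of disjoint atom groups. F is maximal in λ and minimal in P; the
one-particle potential simply adds +λ_i to the SCC shift of every atom in
group i, so ∂F/∂λ_i = C_i − C_i⁰ at the inner-loop solution. The outer
search is a damped Newton iteration on the residual with a finite-difference
Jacobian (step 1e−4) and a residual-norm line search that degrades to
gradient ascent; default residual tolerance 1e−6 e, at most 60 outer
iterations. Unreachable targets (beyond a group's electron capacity) return
a flagged result with the residual rather than raising. Only
Mulliken-population constraint functionals are implemented; user-facing
configuration accepts either population or net-charge targets and converts
internally. Geometry relaxation under constraints is out of scope, so no
force-based optimizer is included.

## Implicit solvation

Monopole (L_max = 0) generalized Born / ALPB:

```
δG_diel = f(ε) Σ_A q_A X_A,   X_A = Σ_B q_B (1/f_kernel(R_AB,a_A,a_B) + α/(ε·A_det))
f(ε) = −½(ε−1)/(ε+α),  α = 0.571214  (α = 0 in the ideal-conductor limit)
```

The ALPB correction is written α/(ε·A_det) so that it vanishes in the
conductor limit and plain GB is recovered — the physically consistent
linearized-Poisson–Boltzmann form. Kernels:

* Still: `f = sqrt(R² + a_A a_B exp(−R²/(4 a_A a_B)))`;
* P16: `f = R + √(a_A a_B)·(1 + ζR/(16√(a_A a_B)))^−16`, ζ = 1.028 — an
  order-16 rational surrogate of the exponential co-screening sharing the
  Born (R→0) and Coulomb (R→∞) limits with Still.

Born radii: Hawkins–Cramer–Truhlar pairwise descreening integrals
(closed form, validated against direct volume quadrature) rescaled through
the GB^OBC II tanh correction with the published coefficient triple
(1.0, 0.8, 4.85). The radius offset is zero by convention here, so an
isolated atom has a_A = ρ_A exactly; descreening scale factors are 1 for the
synthetic elements. A_det (the electrostatic size) defaults to twice the
maximal distance from the geometric center plus the largest Born radius — a
documented stand-in, overridable in configuration. δG_diel is quadratic in
the charges, so its derivative 2f(ε)(GΔq)_A feeds the SCC shift; ε = 1
reproduces the vacuum energy to 1e−10. Nonpolar/cavitation terms and salt
screening are not implemented.

## Linear-response excitations

Mulliken transition charges
`q_A^{ia} = ½ Σ_{μ∈A} Σ_ν (c_{iμ}S_{μν}c_{aν} + c_{iν}S_{νμ}c_{aμ})`
compress the coupling matrix. Closed-shell spin adaptation of the
spin-resolved coupling by the standard ± magnetization combination gives

* singlet: `K = 2 qᵀ γ q`;
* triplet: `K = 2 qᵀ diag(W) q` (on-site magnetization coupling);
* optionally `−x_c·q^{ij} γ^CAM q^{ab}` with a user-supplied long-range
  kernel table (no long-range parametrization ships; x_c ∈ {0, 1}).

The hermitian RPA problem is solved through
`Ω² = eig[(A−B)^{½}(A+B)(A−B)^{½}]` with A = diag(ω_ia) + K, B = K; the TDA
diagonalizes A alone. Eigenvectors are normalized per the RPA metric,
(X+Y)·(X−Y) = 1. Solvers are dense — appropriate at the problem sizes this
package targets; iterative (ARPACK/Stratmann-style) machinery is not
included, and dense solutions are verified against a brute-force solve of
the full non-hermitian 2N×2N system. Negative Ω² roots raise an instability
error naming the offending root. Oscillator strengths use the dipole-length
form `μ_I = Σ_A R_A Σ_{ia} q_A^{ia}(X+Y)_{ia}`, `f_I = (2/3)·Ω_I·|μ_I|²`;
triplet transitions are spin-forbidden (f = 0).

## ΔSCF and the corresponding orbital transformation

The lowest singlet excited state comes from two occupation-constrained
spin-unrestricted SCC calculations: the triplet determinant (HOMO and LUMO
singly occupied, parallel spins) and the mixed determinant (promotion within
one spin channel), combined by the Ziegler sum rule `E_s = 2E_m − E_t`,
which holds to machine precision by construction. Occupations are pinned
across SCC iterations by maximum-overlap assignment against the initial
(ground-state) orbitals; a degenerate HOMO or LUMO is rejected with a clear
error rather than averaged over.

Transition dipoles between the separately optimized determinants use the
COT: the SVD `C_g†SC_e = UΣV†` of the occupied–occupied overlap rotates both
sets into pairwise maximally overlapping form (the rotated overlap is
diagonal with the singular values); the TDM is the cofactor-weighted sum
`Σ_k (Π_{l≠k} σ_l) Σ_A R_A q_A^{(g̃_k, ẽ_k)}`. It is invariant under unitary
mixing of either occupied set, and reduces to the direct evaluation for
identical determinants.

## Synthetic parameter set and fixtures

The built-in set defines two calibration elements — `X` (one 1s electron,
ζ = 1.2, ε_s = −0.25 Ha, U = 0.42 Ha, U^d = −0.16 Ha, W = −0.07 Ha,
hydrogen-class) and `Y` (2s²2p⁴-like, ζ_s = 1.6/ζ_p = 1.3,
ε = −0.60/−0.26 Ha, U = 0.38/0.36 Ha, U^d = −0.14 Ha, W = −0.04 Ha) — with
values chosen once to sit in the range typical of first-row tight-binding
parametrizations (hardness a few tenths of a hartree, negative Hubbard
derivatives, bonded overlaps of order 0.3–0.6). Overlap channels are the
closed-form 1s/2p Slater two-center integrals evaluated through the
prolate-spheroidal auxiliary functions A_n/B_n; H⁰ channels follow the
extended-Hückel rule `H = 1.75·S·(ε_μ+ε_ν)/2` with the constant fixed so
fixtures are stable; tables use grid spacing 0.05 bohr × 240 points
(12 bohr). On-site multipole integrals are the analytic one-center values
(D = 32(ζ_s³ζ_p⁵)^½/(ζ_s+ζ_p)⁵, Q = 4.5/ζ_p²). The repulsive is
`a·e^(−2r)(1−r/r_c)³` with r_c = 3.5 bohr and a = 0.1·√(q⁰_Aq⁰_B) Ha,
sampled onto the `.skf` spline representation (exponential head, cubic
knots, fifth-order terminal segment vanishing with two derivatives at the
cutoff).

Fixture molecules (X₂ at 2.0 bohr; XY⁻ at 2.2 bohr — 8 electrons, clean
closed shell; bent XY₂ with 1.9 bohr bonds at 104°; the X₃ triangle; the
centrosymmetric X₄ chain) are calibration objects spanning the code paths:
symmetry-forced zero charges, heteronuclear transfer, degenerate levels,
fractional occupations, parity selection rules. They emulate no real
chemistry: passing tests demonstrates the correctness of the implemented
mathematics (kernels, fixed points, sum rules, limits), not the predictive
accuracy of any parametrization on real molecules — transferable repulsive
potentials, confinement-optimized basis functions and element-specific
fitted scalings are exactly what the synthetic set does not provide.

## Numerics

* **γ evaluation.** γ is represented as a sum of `exp(−tR−gR²)·(Laurent
  polynomial)` terms, closed under d/dR, giving analytic radial derivatives
  to 4th order. Nearly equal decay constants make the closed-form
  coefficients cancel catastrophically; below a relative τ-difference of
  1e−4 evaluation switches to 35-digit arithmetic. Below R = 1e−3 bohr the
  even Taylor series (coefficients computed once in high precision and
  cached) replaces the direct forms. Γ = (∂γ/∂U_A)·U_A^d uses a centered
  difference with relative step 1e−6 in 50-digit arithmetic — exact for
  practical purposes (~1e−12) and automatically correct for the damped
  variant where the exponent depends on U. γ/Γ matrices are built once per
  geometry, not per SCC iteration.
* **Table interpolation.** Piecewise polynomial through 8 neighboring grid
  points; beyond the last point a fifth-order tail decays to zero (with two
  matched derivatives) over 0.25 bohr; distances beyond the tail raise a
  range error — no extrapolation.
* **SCC.** Linear mixing (default 0.2) on the concatenated moment vector
  (Δq, and Δd/ΔQ in multipole mode), optional Anderson acceleration of
  depth 4; convergence at max|Δ| < 1e−8, at most 200 iterations;
  non-convergence is flagged on the state, not raised. Atom-resolved
  electrostatics by default (U of the highest occupied shell); a
  shell-resolved variant is available for the DFTB2 monopole model.
* **Occupations.** kT = 0: aufbau with equal fractional filling over levels
  degenerate within 1e−10 Ha; kT > 0: Fermi–Dirac with the level found by
  bisection, occupations summing to the electron count to 1e−12.
* **Degenerate inputs.** Coincident atoms, non-positive-definite overlaps,
  electron counts beyond basis capacity, periodic geometries and l > 1
  shells are all rejected with typed errors carrying stable codes.

## Units and conventions

Hartree/bohr internally everywhere; Å only at the XYZ/gen boundary and in
result records, which echo energies in eV and kcal/mol (CODATA 2018
factors). Atom indices are 1-based in all user-facing output and
configuration. Δq is the *population* fluctuation; reported partial charges
are −Δq. The energy record keys are E_DFTB1 (band energy tr(PH⁰)), E_rep,
E_2nd, E_3rd, E_solv, E_constraint; they sum to E_total by definition, so
the repulsive term is reported separately from the first-order band term.

## Problem sizes

The shipped fixtures span 2–4 atoms (2–10 basis functions, transition
spaces up to 8×8), where dense solvers and the brute-force oracles (2N×2N
response systems, quadrature kernels, penalty sweeps) are the appropriate
tool; the full test suite and the acceptance script each complete in well
under a minute on one CPU.

## Known limitations

Cluster geometries only (no periodicity, k-points or Ewald sums); no
analytic nuclear gradients (energies are smooth, so finite differences
work); closed-shell restricted ground states (spin enters only via ΔSCF
and the triplet response channel); no dispersion or hydrogen-bond
corrections; no hybrid/range-separated parametrizations shipped (the
exchange-like response term accepts a user-supplied long-range kernel
table); the L_max > 0 polarizable-continuum solver, nonadiabatic couplings
and transport extensions are out of scope. The classic (non-extended)
`.skf` dialect only; f shells and l > 1 synthetic elements unsupported.
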