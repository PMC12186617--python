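"""Time-independent excited states: Delta-SCF with the Ziegler sum rule.

Two spin-unrestricted, occupation-constrained SCC calculations give the
lowest triplet determinant (E_t: HOMO and LUMO singly occupied with parallel
spins) and the spin-mixed determinant (E_m: the promoted electron keeps the
opposite spin). The singlet excited-state energy follows from the sum rule

    E_s = 2 E_m - E_t.

Occupation patterns are held fixed across SCC iterations by maximum-overlap
assignment against the initial (ground-state) orbitals. Transition dipole
moments between the separately optimized determinants use the corresponding
orbital transformation (COT): an SVD of the occupied-occupied overlap rotates
both orbital sets into maximally pairwise-overlapping form, after which
Mulliken transition charges of the corresponding pairs, weighted by the
cofactor products of the singular values, assemble the dipole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NumericError
from .scc import (
    DEGENERACY_TOL,
    SCCOptions,
    _solve,
    build_gamma_matrices,
    build_h0_s,
    density_matrix,
    mulliken_charges,
    n_valence_electrons,
    repulsive_energy,
    scc_loop,
)


@dataclass
class UnrestrictedState:
    c_up: np.ndarray
    c_dn: np.ndarray
    e_up: np.ndarray
    e_dn: np.ndarray
    occ_up: np.ndarray
    occ_dn: np.ndarray
    energy_terms: dict
    dq: np.ndarray
    magnetization: np.ndarray
    converged: bool
    n_iterations: int
    basis: object
    overlap: np.ndarray


def _max_overlap_occupations(c_ref_occ, s, c_new, n_occ_new):
    """Occupy the new orbitals that overlap the reference-occupied space most.

    Greedy assignment on the projection weights; returns an index list of
    length ``n_occ_new``.
    """
    proj = c_ref_occ.T @ s @ c_new          # (n_ref_occ, n_orb)
    weights = np.sum(proj ** 2, axis=0)     # overlap weight per new orbital
    order = np.argsort(-weights, kind="stable")
    return sorted(order[:n_occ_new].tolist())


def scc_fixed_occupation(
    geometry,
    params,
    model: str,
    occ_up_ref: list[int],
    occ_dn_ref: list[int],
    reference_orbitals: np.ndarray,
    options: SCCOptions | None = None,
) -> UnrestrictedState:
    """Spin-unrestricted SCC with the occupation pattern pinned by maximum
    overlap with ``reference_orbitals`` columns ``occ_*_ref``."""
    opts = options or SCCOptions()
    if model not in ("dftb1", "dftb2", "dftb3"):
        raise ConfigurationError(f"unknown model {model!r}")
    h0, s, basis = build_h0_s(geometry, params)
    kernel = opts.kernel()
    gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
    w_const = np.array([params.element(sym).spin_constant
                        for sym in geometry.symbols])
    n_atoms = geometry.n_atoms
    e_rep = repulsive_energy(geometry, params)
    ref_up = reference_orbitals[:, occ_up_ref]
    ref_dn = reference_orbitals[:, occ_dn_ref]

    dq = np.zeros(n_atoms)
    mag = np.zeros(n_atoms)
    converged = False
    n_iter = 0
    p_up = p_dn = None
    c_up = c_dn = e_up = e_dn = None
    iu = id_ = None
    for n_iter in range(1, opts.max_iterations + 1):
        v_charge = np.zeros(n_atoms)
        if model in ("dftb2", "dftb3"):
            v_charge = gamma_mat @ dq
        if model == "dftb3":
            v_charge = v_charge + (2.0 / 3.0) * dq * (big_gamma @ dq) \
                + (big_gamma.T @ (dq * dq)) / 3.0
        v_spin = w_const * mag
        new_p = {}
        for sigma, (v_s, ref) in {"up": (v_spin, ref_up),
                                  "dn": (-v_spin, ref_dn)}.items():
            v_tot = v_charge + v_s
            w = np.zeros_like(h0)
            for a in range(n_atoms):
                sl = basis.atom_slice(a)
                idx = np.arange(sl.start, sl.stop)
                w[idx, idx] = v_tot[a]
            h = h0 + 0.5 * (w @ s + s @ w)
            eps, c = _solve(h, s)
            occ_idx = _max_overlap_occupations(ref, s, c, ref.shape[1])
            occ = np.zeros(len(eps))
            occ[occ_idx] = 1.0
            new_p[sigma] = (eps, c, occ, density_matrix(c, occ))
        e_up, c_up, occ_up, p_up_new = new_p["up"]
        e_dn, c_dn, occ_dn, p_dn_new = new_p["dn"]
        dq_up, _ = mulliken_charges(p_up_new, s, basis, params)
        dq_dn, _ = mulliken_charges(p_dn_new, s, basis, params)
        # per-spin "fluctuations" measured against half the reference density
        q0 = np.array([params.element(sym).valence_electrons
                       for sym in geometry.symbols])
        pop_up = dq_up + q0
        pop_dn = dq_dn + q0
        dq_new = pop_up + pop_dn - q0
        mag_new = pop_up - pop_dn
        delta = max(np.max(np.abs(dq_new - dq)), np.max(np.abs(mag_new - mag)))
        mix = opts.mixing
        dq = dq + mix * (dq_new - dq)
        mag = mag + mix * (mag_new - mag)
        p_up, p_dn = p_up_new, p_dn_new
        iu, id_ = occ_up, occ_dn
        if delta < opts.tolerance:
            converged = True
            dq, mag = dq_new, mag_new
            break

    e_band = float(np.einsum("ij,ji->", p_up + p_dn, h0))
    e2 = e3 = 0.0
    if model in ("dftb2", "dftb3"):
        e2 = float(0.5 * dq @ gamma_mat @ dq)
    if model == "dftb3":
        e3 = float(np.einsum("a,ab,b->", dq * dq, big_gamma, dq) / 3.0)
    e_spin = float(0.5 * np.sum(w_const * mag ** 2))
    terms = {
        "E_DFTB1": e_band, "E_rep": e_rep, "E_2nd": e2, "E_3rd": e3,
        "E_spin": e_spin, "E_solv": 0.0, "E_constraint": 0.0,
    }
    terms["E_total"] = e_band + e_rep + e2 + e3 + e_spin
    return UnrestrictedState(
        c_up=c_up, c_dn=c_dn, e_up=e_up, e_dn=e_dn,
        occ_up=iu, occ_dn=id_, energy_terms=terms, dq=dq,
        magnetization=mag, converged=converged, n_iterations=n_iter,
        basis=basis, overlap=s,
    )


def delta_dftb(geometry, params, model: str = "dftb2",
               options: SCCOptions | None = None):
    """(E_t, E_m, E_s) from the two occupation-constrained determinants.

    Requires an even electron count and a non-degenerate HOMO and LUMO in
    the closed-shell ground state.
    """
    opts = options or SCCOptions()
    ground = scc_loop(geometry, params, model, opts)
    nelec = n_valence_electrons(geometry, params)
    if abs(nelec - round(nelec)) > 1e-9 or int(round(nelec)) % 2 != 0:
        raise ConfigurationError("Delta-SCF needs an even electron count")
    n_occ = int(round(nelec)) // 2
    eps = ground.mo_energies
    if n_occ >= len(eps):
        raise ConfigurationError("no LUMO available")
    if abs(eps[n_occ - 1] - eps[n_occ]) < 1e-8:
        raise ConfigurationError("vanishing HOMO-LUMO gap")
    if n_occ >= 2 and abs(eps[n_occ - 1] - eps[n_occ - 2]) < DEGENERACY_TOL:
        raise ConfigurationError(
            "degenerate HOMO: occupation-constrained Delta-SCF is ill-defined"
        )
    if n_occ + 1 < len(eps) and abs(eps[n_occ + 1] - eps[n_occ]) < DEGENERACY_TOL:
        raise ConfigurationError(
            "degenerate LUMO: occupation-constrained Delta-SCF is ill-defined"
        )
    c0 = ground.mo_coefficients
    homo, lumo = n_occ - 1, n_occ
    base_occ = list(range(n_occ))
    # triplet: both unpaired electrons spin-up
    st_t = scc_fixed_occupation(
        geometry, params, model,
        occ_up_ref=base_occ + [lumo],
        occ_dn_ref=base_occ[:-1],
        reference_orbitals=c0, options=opts,
    )
    # mixed determinant: promotion within the spin-up channel
    st_m = scc_fixed_occupation(
        geometry, params, model,
        occ_up_ref=base_occ[:-1] + [lumo],
        occ_dn_ref=base_occ,
        reference_orbitals=c0, options=opts,
    )
    e_t = st_t.energy_terms["E_total"]
    e_m = st_m.energy_terms["E_total"]
    e_s = 2.0 * e_m - e_t
    return {
        "E_t": e_t, "E_m": e_m, "E_s": e_s,
        "ground": ground, "triplet": st_t, "mixed": st_m,
        "converged": bool(st_t.converged and st_m.converged
                          and ground.converged),
    }


def cot_transition_dipole(c_ground_occ, c_excited_occ, s, geometry, basis):
    """Transition dipole between two determinants via the COT.

    SVD of O = C_g^T S C_e rotates both occupied sets; the dipole is the
    singular-value-cofactor-weighted sum of corresponding-pair Mulliken
    transition dipoles. A singular overlap (orthogonal determinants) yields
    a zero vector with a warning.
    """
    from .excited import pair_transition_charge

    o = c_ground_occ.T @ s @ c_excited_occ
    u, sing, vt = np.linalg.svd(o)
    g_rot = c_ground_occ @ u
    e_rot = c_excited_occ @ vt.T
    n_pair = len(sing)
    if np.min(sing) < 1e-12 and n_pair > 1:
        # more than one vanishing singular value -> dipole-forbidden at this level
        if np.sort(sing)[1] < 1e-12:
            warnings.warn("determinants differ by more than one orbital; "
                          "COT transition dipole vanishes", stacklevel=2)
            return np.zeros(3)
    dip = np.zeros(3)
    for k_pair in range(n_pair):
        cof = np.prod(np.delete(sing, k_pair)) if n_pair > 1 else 1.0
        q_pair = pair_transition_charge(
            g_rot[:, k_pair], e_rot[:, k_pair], s, basis
        )
        dip += cof * (q_pair @ geometry.positions)
    return dip


def cot_overlap_diagonal(c_ground_occ, c_excited_occ, s):
    """Rotated occupied-occupied overlap (diagonal with the singular values)."""
    o = c_ground_occ.T @ s @ c_excited_occ
    u, sing, vt = np.linalg.svd(o)
    return (c_ground_occ @ u).T @ s @ (c_excited_occ @ vt.T), sing
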