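"""Linear-response TD-DFTB excitations (RPA and Tamm-Dancoff).

The response eigenproblem

    [A  B] [X]       [ 1  0] [X]
    [B  A] [Y] = Omega [ 0 -1] [Y]

with A = diag(omega_ia) + K, B = K (hermitian closed-shell case) is solved
through the reduced symmetric problem

    Omega^2 = eig[ (A-B)^(1/2) (A+B) (A-B)^(1/2) ]

The coupling matrix K is compressed with Mulliken transition charges

    q_A^{ia} = 1/2 sum_{mu in A} sum_nu (c_{i mu} S_{mu nu} c_{a nu}
                                         + c_{i nu} S_{nu mu} c_{a mu})

singlet channel: K = 2 q^T gamma q'; triplet channel: the Coulomb part is
replaced by the on-site magnetization coupling 2 q^T W q'. An optional
long-range exchange-like term -x_c q^{ij} gamma_CAM q^{ab} requires a
user-supplied long-range kernel table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    CapabilityError,
    ConfigurationError,
    ConsistencyError,
    NumericError,
)


@dataclass
class ExcitationSet:
    omegas: np.ndarray                 # (n_states,), hartree
    xpy: np.ndarray                    # (n_states, n_trans)  X+Y (or X for TDA)
    xmy: np.ndarray                    # (n_states, n_trans)  X-Y (or X for TDA)
    pairs: list[tuple[int, int]]       # transition-space index -> (i, a)
    channel: str                       # 'singlet' | 'triplet'
    method: str                        # 'rpa' | 'tda'
    transition_dipoles: np.ndarray | None = None   # (n_states, 3), e*bohr
    oscillator_strengths: np.ndarray | None = None


def transition_charges(c, s, occupied, virtual, basis) -> np.ndarray:
    """Mulliken transition charges q_A^{ia}.

    Returns an (n_atoms, n_occ*n_virt) matrix; transition-space columns are
    ordered as (i, a) with i outer, a inner. MOs must be S-orthonormal.
    """
    c = np.asarray(c)
    ortho = c.T @ s @ c
    if np.max(np.abs(ortho - np.eye(c.shape[1]))) > 1e-8:
        raise ConsistencyError("MO coefficients are not S-orthonormal")
    sc = s @ c
    n_atoms = basis.n_atoms
    q = np.zeros((n_atoms, len(occupied) * len(virtual)))
    for col, (i, a) in enumerate((i, a) for i in occupied for a in virtual):
        contrib = 0.5 * (c[:, i] * sc[:, a] + c[:, a] * sc[:, i])
        for at in range(n_atoms):
            sl = basis.atom_slice(at)
            q[at, col] = contrib[sl].sum()
    return q


def pair_transition_charge(x, y, s, basis) -> np.ndarray:
    """Transition charge vector between two orbital coefficient vectors."""
    contrib = 0.5 * (x * (s @ y) + y * (s @ x))
    return np.array([contrib[basis.atom_slice(at)].sum()
                     for at in range(basis.n_atoms)])


def coupling_matrix(
    q: np.ndarray,
    gamma_mat: np.ndarray,
    spin_constants: np.ndarray,
    channel: str = "singlet",
    x_c: int = 0,
    gamma_cam: np.ndarray | None = None,
    q_oo: np.ndarray | None = None,
    q_vv: np.ndarray | None = None,
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Spin-adapted coupling matrix K over transition space.

    singlet: K = 2 q^T gamma q; triplet: K = 2 q^T diag(W) q. With x_c = 1 an
    exchange-like term -q^{ij} gamma_CAM q^{ab} is subtracted (requires the
    long-range kernel plus occupied-occupied / virtual-virtual charges).
    """
    if channel not in ("singlet", "triplet"):
        raise ConfigurationError(f"unknown spin channel {channel!r}")
    if channel == "singlet":
        k = 2.0 * q.T @ gamma_mat @ q
    else:
        k = 2.0 * q.T @ (spin_constants[:, None] * q)
    if x_c:
        if gamma_cam is None or q_oo is None or q_vv is None or pairs is None:
            raise ConfigurationError(
                "x_c = 1 requires a long-range gamma_CAM table and the "
                "occupied-occupied / virtual-virtual transition charges"
            )
        occ = sorted({i for i, _ in pairs})
        virt = sorted({a for _, a in pairs})
        o_index = {i: k_ for k_, i in enumerate(occ)}
        v_index = {a: k_ for k_, a in enumerate(virt)}
        n_t = len(pairs)
        for col1, (i, a) in enumerate(pairs):
            for col2, (j, b) in enumerate(pairs):
                qij = q_oo[:, o_index[i] * len(occ) + o_index[j]]
                qab = q_vv[:, v_index[a] * len(virt) + v_index[b]]
                k[col1, col2] -= x_c * qij @ gamma_cam @ qab
    return 0.5 * (k + k.T)


def casida_solve(
    omega_ia: np.ndarray,
    k: np.ndarray,
    n_states: int,
    method: str = "rpa",
    pairs: list[tuple[int, int]] | None = None,
    channel: str = "singlet",
) -> ExcitationSet:
    """Solve the response problem; dense, lowest n_states returned sorted.

    RPA uses the symmetric reduced form; negative Omega^2 roots raise a
    NumericError naming the offending root (triplet/RPA instability).
    """
    w = np.asarray(omega_ia, dtype=float)
    n_t = len(w)
    if np.any(w <= 0):
        raise ConfigurationError("all orbital energy differences must be > 0")
    if n_states > n_t:
        raise ConfigurationError(
            f"requested {n_states} states but transition space has {n_t}"
        )
    a_mat = np.diag(w) + k
    if method == "tda":
        vals, vecs = scipy.linalg.eigh(a_mat)
        if np.any(vals <= 0):
            idx = int(np.argmin(vals))
            raise NumericError(
                f"TDA instability: root {idx} has Omega = {vals[idx]:.6e}"
            )
        sel = np.argsort(vals)[:n_states]
        omegas = vals[sel]
        x = vecs[:, sel].T
        return ExcitationSet(
            omegas=omegas, xpy=x.copy(), xmy=x.copy(),
            pairs=pairs or [], channel=channel, method="tda",
        )
    if method != "rpa":
        raise ConfigurationError(f"unknown method {method!r}")
    amb = a_mat - k            # = diag(w)
    apb = a_mat + k
    # (A-B)^(1/2) via eigendecomposition (A-B must be positive definite)
    vals_mb, vecs_mb = scipy.linalg.eigh(amb)
    if np.any(vals_mb <= 0):
        idx = int(np.argmin(vals_mb))
        raise NumericError(
            f"RPA instability: (A-B) eigenvalue {vals_mb[idx]:.6e} at root {idx}"
        )
    sq = vecs_mb @ np.diag(np.sqrt(vals_mb)) @ vecs_mb.T
    sqinv = vecs_mb @ np.diag(1.0 / np.sqrt(vals_mb)) @ vecs_mb.T
    m = sq @ apb @ sq
    m = 0.5 * (m + m.T)
    w2, z = scipy.linalg.eigh(m)
    if np.any(w2 <= 0):
        idx = int(np.argmin(w2))
        raise NumericError(
            f"RPA instability: Omega^2 = {w2[idx]:.6e} at root {idx}"
        )
    order = np.argsort(w2)[:n_states]
    omegas = np.sqrt(w2[order])
    xpy = np.zeros((n_states, n_t))
    xmy = np.zeros((n_states, n_t))
    for s_i, (o_idx, om) in enumerate(zip(order, omegas)):
        zz = z[:, o_idx]
        xpy[s_i] = (sq @ zz) / np.sqrt(om)
        xmy[s_i] = (sqinv @ zz) * np.sqrt(om)
    return ExcitationSet(
        omegas=omegas, xpy=xpy, xmy=xmy, pairs=pairs or [],
        channel=channel, method="rpa",
    )


def oscillator_strengths(
    exc: ExcitationSet, q: np.ndarray, geometry
) -> ExcitationSet:
    """Transition dipoles and oscillator strengths (dipole-length form).

    mu_I = sum_A R_A sum_{ia} q_A^{ia} (X+Y)_{ia};  f_I = (2/3) Omega |mu|^2.
    Triplet transitions are spin-forbidden: f = 0.
    """
    n_states = len(exc.omegas)
    dip = np.zeros((n_states, 3))
    f = np.zeros(n_states)
    if exc.channel == "singlet":
        for s_i in range(n_states):
            q_state = q @ exc.xpy[s_i]          # (n_atoms,)
            dip[s_i] = q_state @ geometry.positions
            f[s_i] = (2.0 / 3.0) * exc.omegas[s_i] * float(dip[s_i] @ dip[s_i])
    exc.transition_dipoles = dip
    exc.oscillator_strengths = f
    return exc


def excitation_spectrum(
    geometry,
    params,
    model: str = "dftb2",
    n_states: int = 5,
    method: str = "rpa",
    channel: str = "singlet",
    options=None,
    x_c: int = 0,
    gamma_cam: np.ndarray | None = None,
):
    """Ground-state SCC + linear response in one call.

    Returns (ground_state, ExcitationSet).
    """
    from .scc import build_gamma_matrices, scc_loop, SCCOptions

    opts = options or SCCOptions()
    ground = scc_loop(geometry, params, model, opts)
    occ_idx = [i for i, o in enumerate(ground.occupations) if o > 1.0 + 1e-8]
    virt_idx = [i for i, o in enumerate(ground.occupations) if o < 1.0 - 1e-8]
    # require a clean closed-shell reference
    if not occ_idx or not virt_idx:
        raise ConfigurationError("no occupied-virtual transition space")
    if any(min(abs(o), abs(o - 2.0)) > 1e-8 for o in ground.occupations):
        raise ConfigurationError(
            "fractional ground-state occupations: linear response requires "
            "a closed-shell reference"
        )
    pairs = [(i, a) for i in occ_idx for a in virt_idx]
    if n_states > len(pairs):
        raise ConfigurationError(
            f"requested {n_states} states but transition space has {len(pairs)}"
        )
    q = transition_charges(
        ground.mo_coefficients, ground.overlap, occ_idx, virt_idx, ground.basis
    )
    gamma_mat, _ = build_gamma_matrices(geometry, params, opts.kernel())
    w_const = np.array([params.element(s).spin_constant
                        for s in geometry.symbols])
    kwargs = {}
    if x_c:
        q_oo = transition_charges(ground.mo_coefficients, ground.overlap,
                                  occ_idx, occ_idx, ground.basis)
        q_vv = transition_charges(ground.mo_coefficients, ground.overlap,
                                  virt_idx, virt_idx, ground.basis)
        kwargs = {"q_oo": q_oo, "q_vv": q_vv, "pairs": pairs,
                  "gamma_cam": gamma_cam}
    k = coupling_matrix(q, gamma_mat, w_const, channel, x_c, **kwargs)
    omega_ia = np.array([
        ground.mo_energies[a] - ground.mo_energies[i] for i, a in pairs
    ])
    exc = casida_solve(omega_ia, k, n_states, method, pairs, channel)
    exc = oscillator_strengths(exc, q, geometry)
    return ground, exc
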