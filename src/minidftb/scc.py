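"""Self-consistent-charge engine: H0/S assembly, SCC loop, total energies.

Model levels:

* ``dftb1`` -- a single diagonalization of H0; charge fluctuations are
  reported but not fed back.
* ``dftb2`` -- second-order monopole electrostatics: E2 = 1/2 sum dq gamma dq.
* ``dftb3`` -- adds the third-order term E3 = 1/3 sum dq_A^2 dq_B Gamma_AB.

The SCC Hamiltonian is built variationally as H = H0 + 0.5 (W S + S W) with a
block-diagonal on-site potential matrix W; in monopole mode W_A = V_A * I,
which reduces to the familiar 0.5 * S_{mu nu} (V_A + V_B) shift. The same
construction carries the multipole potentials, an external (constraint)
potential, and the implicit-solvent shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    CapacityError,
    ConfigurationError,
    NumericError,
    TableRangeError,
)
from .gamma import GammaKernel, gamma_pair
from .geometry import Geometry
from .params import ParameterSet
from .skf import evaluate_repulsive
from .sktransform import sk_rotate
from .units import EV_PER_HARTREE, KCALMOL_PER_HARTREE

DEGENERACY_TOL = 1e-10  # hartree; levels closer than this share electrons


# ------------------------------------------------------------------- basis

@dataclass
class BasisMap:
    """Mapping between basis orbitals and (atom, shell, m) labels."""

    symbols: list[str]
    atom_of: np.ndarray               # orbital -> atom index
    shell_of: np.ndarray              # orbital -> shell index within atom
    l_of: np.ndarray                  # orbital -> angular momentum
    slices: list[slice]               # atom -> orbital slice

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def n_basis(self) -> int:
        return len(self.atom_of)

    def atom_slice(self, a: int) -> slice:
        return self.slices[a]

    def local_shell_orbitals(self, a: int, l: int):
        """Local (within-atom) orbital indices of the first shell with the
        given angular momentum, or None."""
        sl = self.slices[a]
        loc = [k for k in range(sl.stop - sl.start)
               if self.l_of[sl.start + k] == l]
        if not loc:
            return None
        return loc[: 2 * l + 1]


def build_basis(geometry: Geometry, params: ParameterSet) -> BasisMap:
    atom_of, shell_of, l_of, slices = [], [], [], []
    start = 0
    for a, sym in enumerate(geometry.symbols):
        el = params.element(sym)
        for si, sh in enumerate(el.shells):
            for _ in range(sh.n_orbitals):
                atom_of.append(a)
                shell_of.append(si)
                l_of.append(sh.l)
        slices.append(slice(start, start + el.n_orbitals))
        start += el.n_orbitals
    return BasisMap(
        symbols=list(geometry.symbols),
        atom_of=np.array(atom_of),
        shell_of=np.array(shell_of),
        l_of=np.array(l_of),
        slices=slices,
    )


def build_h0_s(
    geometry: Geometry, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, BasisMap]:
    """Assemble the non-SCC Hamiltonian and overlap matrices.

    Diagonal blocks: on-site energies (diagonal), unit overlap. Off-diagonal
    blocks: Slater-Koster rotations of the tabulated bond integrals.
    """
    basis = build_basis(geometry, params)
    n = basis.n_basis
    h0 = np.zeros((n, n))
    s = np.eye(n)
    for a, sym in enumerate(geometry.symbols):
        el = params.element(sym)
        k = basis.slices[a].start
        for sh in el.shells:
            for _ in range(sh.n_orbitals):
                h0[k, k] = sh.energy
                k += 1
    for a in range(geometry.n_atoms):
        el_a = params.element(geometry.symbols[a])
        for b in range(a + 1, geometry.n_atoms):
            el_b = params.element(geometry.symbols[b])
            d = geometry.positions[b] - geometry.positions[a]
            r = float(np.linalg.norm(d))
            direction = d / r
            t_ab = params.table(el_a.symbol, el_b.symbol)
            t_ba = params.table(el_b.symbol, el_a.symbol)
            if r > t_ab.r_max or r > t_ba.r_max:
                raise TableRangeError(
                    f"atoms {a + 1} and {b + 1} at {r:.3f} bohr exceed the "
                    f"{el_a.symbol}-{el_b.symbol} table range"
                )
            off_a = basis.slices[a].start
            off_b = basis.slices[b].start
            la_off = 0
            for ia, sh_a in enumerate(el_a.shells):
                lb_off = 0
                for ib, sh_b in enumerate(el_b.shells):
                    for mat, target in (("H", h0), ("S", s)):
                        block = sk_rotate(
                            t_ab, t_ba, sh_a.l, sh_b.l, direction, r, mat
                        )
                        rows = slice(off_a + la_off, off_a + la_off + sh_a.n_orbitals)
                        cols = slice(off_b + lb_off, off_b + lb_off + sh_b.n_orbitals)
                        target[rows, cols] = block
                        target[cols, rows] = block.T
                    lb_off += sh_b.n_orbitals
                la_off += sh_a.n_orbitals
    return h0, s, basis


# --------------------------------------------------------------- charges

def mulliken_charges(P, S, basis: BasisMap, params: ParameterSet):
    """Atomic Mulliken fluctuations dq_A and shell-resolved populations.

    dq_A = sum_{mu in A} (P S)_{mu mu} - q_A^0.
    """
    diag = np.einsum("ij,ji->i", P, S)
    n_atoms = basis.n_atoms
    dq = np.zeros(n_atoms)
    shell_pops: list[np.ndarray] = []
    for a in range(n_atoms):
        el = params.element(basis.symbols[a])
        sl = basis.atom_slice(a)
        pops = np.zeros(len(el.shells))
        for k in range(sl.start, sl.stop):
            pops[basis.shell_of[k]] += diag[k]
        shell_pops.append(pops)
        dq[a] = pops.sum() - el.valence_electrons
    return dq, shell_pops


def fermi_fill(mo_energies, n_electrons: float, kT: float = 0.0,
               max_occ: float = 2.0):
    """Occupations and Fermi level for a level spectrum.

    kT = 0: aufbau with equal fractional filling over levels degenerate
    within DEGENERACY_TOL. kT > 0: Fermi-Dirac occupations, Fermi level by
    bisection; occupations sum to the electron count to 1e-12.
    """
    e = np.asarray(mo_energies, dtype=float)
    n_orb = len(e)
    if n_electrons > max_occ * n_orb + 1e-12:
        raise CapacityError(
            f"{n_electrons} electrons exceed capacity {max_occ * n_orb}"
        )
    if n_electrons < 0:
        raise CapacityError("negative electron count")
    order = np.argsort(e, kind="stable")
    occ = np.zeros(n_orb)
    if kT == 0.0:
        remaining = float(n_electrons)
        i = 0
        fermi = e[order[0]] if n_orb else 0.0
        while remaining > 1e-15 and i < n_orb:
            group = [order[i]]
            while (i + len(group) < n_orb
                   and abs(e[order[i + len(group)]] - e[group[0]]) < DEGENERACY_TOL):
                group.append(order[i + len(group)])
            fill = min(remaining, max_occ * len(group))
            for idx in group:
                occ[idx] = fill / len(group)
            fermi = e[group[0]]
            remaining -= fill
            i += len(group)
        return occ, float(fermi)
    lo, hi = e.min() - 30 * kT, e.max() + 30 * kT

    def count(mu):
        x = np.clip((e - mu) / kT, -600.0, 600.0)
        return np.sum(max_occ / (1.0 + np.exp(x)))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if count(mid) < n_electrons:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, abs(mid)):
            break
    mu = 0.5 * (lo + hi)
    occ = max_occ / (1.0 + np.exp(np.clip((e - mu) / kT, -600.0, 600.0)))
    # polish the sum to 1e-12 by scaling within the bisection residual
    total = occ.sum()
    if total > 0:
        occ *= n_electrons / total
    return occ, float(mu)


# --------------------------------------------------------------- gamma

def build_gamma_matrices(geometry: Geometry, params: ParameterSet,
                         kernel: GammaKernel):
    """(gamma_AB, Gamma_AB) matrices over atoms.

    Gamma_AB = dgamma/dU_A * U_A^d (off-diagonal); Gamma_AA = U_A^d, the
    total derivative of the on-site limit gamma_AA(0) = U_A.
    """
    n = geometry.n_atoms
    g = np.zeros((n, n))
    big_g = np.zeros((n, n))
    specs = [params.element(s) for s in geometry.symbols]
    for a in range(n):
        g[a, a] = specs[a].hubbard
        big_g[a, a] = specs[a].hubbard_d
        for b in range(n):
            if a == b:
                continue
            r = geometry.distance(a, b)
            hyd = specs[a].hydrogen_class or specs[b].hydrogen_class
            gv, gd = gamma_pair(
                kernel, specs[a].hubbard, specs[b].hubbard, r,
                hydrogen_pair=hyd, hubbard_derivative_a=specs[a].hubbard_d,
            )
            g[a, b] = gv
            big_g[a, b] = gd
    return g, big_g


def build_shell_gamma(geometry: Geometry, params: ParameterSet,
                      kernel: GammaKernel):
    """Shell-resolved gamma matrix (one row/column per atomic shell)."""
    entries = []  # (atom, shell_index, U)
    specs = [params.element(s) for s in geometry.symbols]
    for a, el in enumerate(specs):
        for si in range(len(el.shells)):
            entries.append((a, si, el.hubbard_u[si]))
    m = len(entries)
    g = np.zeros((m, m))
    for i, (a, _, ua) in enumerate(entries):
        for j, (b, _, ub) in enumerate(entries):
            r = geometry.distance(a, b) if a != b else 0.0
            hyd = specs[a].hydrogen_class or specs[b].hydrogen_class
            damp = kernel.damping(ua, ub, hyd)
            from .gamma import gamma_value
            g[i, j] = gamma_value(ua, ub, r, damp if a != b else 0.0)
    return g, entries


# --------------------------------------------------------------- state

@dataclass
class SCCState:
    mo_coefficients: np.ndarray
    mo_energies: np.ndarray
    occupations: np.ndarray
    density_matrix: np.ndarray
    overlap: np.ndarray
    hamiltonian: np.ndarray
    h0: np.ndarray
    dq: np.ndarray
    shell_populations: list
    energy_terms: dict
    converged: bool
    n_iterations: int
    basis: BasisMap
    fermi_level: float = 0.0
    moments: object | None = None     # MultipoleState when multipole mode on
    lambdas: np.ndarray | None = None

    @property
    def e_total(self) -> float:
        return self.energy_terms["E_total"]

    def energy_record(self) -> dict:
        """JSON-serializable energy breakdown with unit conversions."""
        out = {}
        for key, val in self.energy_terms.items():
            out[key] = {
                "hartree": val,
                "eV": val * EV_PER_HARTREE,
                "kcal/mol": val * KCALMOL_PER_HARTREE,
            }
        return out


@dataclass
class SCCOptions:
    mixing: float = 0.2
    anderson: bool = False
    anderson_depth: int = 4
    tolerance: float = 1e-8
    max_iterations: int = 200
    kT: float = 0.0
    gamma_variant: str = "gamma_h"    # 'plain' | 'gamma_h'
    gamma_zeta: float = 4.0
    shell_resolved: bool = False
    multipole: bool = False
    solvation: object | None = None   # solvation.SolvationModel
    external_potential: np.ndarray | None = None  # per-atom shift (constraints)
    constraint: object | None = None  # constraints.ConstraintSpec with lambdas

    def kernel(self) -> GammaKernel:
        return GammaKernel(variant=self.gamma_variant, zeta=self.gamma_zeta)


def n_valence_electrons(geometry: Geometry, params: ParameterSet) -> float:
    q0 = sum(params.element(s).valence_electrons for s in geometry.symbols)
    return q0 - geometry.net_charge


def repulsive_energy(geometry: Geometry, params: ParameterSet) -> float:
    e = 0.0
    for a in range(geometry.n_atoms):
        for b in range(a + 1, geometry.n_atoms):
            table = params.table(geometry.symbols[a], geometry.symbols[b])
            e += evaluate_repulsive(table, geometry.distance(a, b))
    return e


def _solve(h, s):
    try:
        return scipy.linalg.eigh(h, s)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise NumericError(f"generalized eigensolver failed: {exc}") from exc


def density_matrix(c, occ):
    return (c * occ) @ c.T


def _onsite_w_matrix(basis: BasisMap, params: ParameterSet, v_q,
                     v_d=None, v_Q=None):
    """Block-diagonal on-site potential matrix W for H1 = (W S + S W)/2."""
    n = basis.n_basis
    w = np.zeros((n, n))
    for a in range(basis.n_atoms):
        sl = basis.atom_slice(a)
        idx = np.arange(sl.start, sl.stop)
        w[idx, idx] = v_q[a]
        if v_d is not None:
            el = params.element(basis.symbols[a])
            s_loc = basis.local_shell_orbitals(a, 0)
            p_loc = basis.local_shell_orbitals(a, 1)
            if p_loc is not None and s_loc is not None:
                ds = el.dipole_scale * el.dipole_integral
                for k in range(3):
                    w[sl.start + s_loc[0], sl.start + p_loc[k]] += ds * v_d[a][k]
                    w[sl.start + p_loc[k], sl.start + s_loc[0]] += ds * v_d[a][k]
            if p_loc is not None and v_Q is not None:
                qs = el.quadrupole_scale * el.quadrupole_integral
                vq_t = v_Q[a] - np.eye(3) * np.trace(v_Q[a]) / 3.0
                for i in range(3):
                    for j in range(3):
                        w[sl.start + p_loc[i], sl.start + p_loc[j]] += qs * vq_t[i, j]
    return w


class _AndersonMixer:
    """Anderson acceleration of the SCC fixed-point map (small history)."""

    def __init__(self, beta: float, depth: int):
        self.beta = beta
        self.depth = depth
        self.x_hist: list[np.ndarray] = []
        self.f_hist: list[np.ndarray] = []

    def step(self, x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
        f = x_out - x_in
        self.x_hist.append(x_in.copy())
        self.f_hist.append(f.copy())
        if len(self.x_hist) > self.depth + 1:
            self.x_hist.pop(0)
            self.f_hist.pop(0)
        m = len(self.x_hist) - 1
        if m == 0:
            return x_in + self.beta * f
        df = np.stack([self.f_hist[k + 1] - self.f_hist[k] for k in range(m)], axis=1)
        dx = np.stack([self.x_hist[k + 1] - self.x_hist[k] for k in range(m)], axis=1)
        try:
            theta, *_ = np.linalg.lstsq(df, f, rcond=None)
        except np.linalg.LinAlgError:
            return x_in + self.beta * f
        x_bar = x_in - dx @ theta
        f_bar = f - df @ theta
        return x_bar + self.beta * f_bar


def scc_loop(
    geometry: Geometry,
    params: ParameterSet,
    model: str = "dftb2",
    options: SCCOptions | None = None,
) -> SCCState:
    """Run the SCC iteration (or the single DFTB1 diagonalization).

    Non-convergence is reported through ``converged=False`` on the returned
    state, not as an exception.
    """
    if model not in ("dftb1", "dftb2", "dftb3"):
        raise ConfigurationError(f"unknown model {model!r}")
    opts = options or SCCOptions()
    if opts.shell_resolved and (opts.multipole or model == "dftb3"):
        raise ConfigurationError(
            "shell-resolved electrostatics supports the dftb2 monopole model only"
        )
    from .multipole import (
        MultipoleState,
        build_kernel_table,
        mdftb_energy_and_potentials,
        multipole_moments,
    )

    h0, s, basis = build_h0_s(geometry, params)
    nelec = n_valence_electrons(geometry, params)
    if nelec > 2 * basis.n_basis:
        raise CapacityError("electron count exceeds basis capacity")
    kernel = opts.kernel()
    n_atoms = geometry.n_atoms
    e_rep = repulsive_energy(geometry, params)

    gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
    shell_gamma = shell_entries = None
    if opts.shell_resolved:
        shell_gamma, shell_entries = build_shell_gamma(geometry, params, kernel)
    kernels = build_kernel_table(geometry, params, kernel) if opts.multipole else None

    solv = opts.solvation
    g_solv = None
    if solv is not None:
        from .solvation import solvation_matrix
        g_solv = solvation_matrix(geometry, params, solv)

    def shift_and_energy(dq, shell_pops, moments):
        """Returns (W matrix, electrostatic energy terms dict)."""
        terms = {"E_2nd": 0.0, "E_3rd": 0.0, "E_solv": 0.0, "E_constraint": 0.0}
        v_q = np.zeros(n_atoms)
        v_d = v_Q = None
        if model in ("dftb2", "dftb3"):
            if opts.multipole:
                mp_break, vq_m, v_d, v_Q = mdftb_energy_and_potentials(
                    moments, kernels
                )
                terms["E_2nd"] = mp_break["total"]
                terms["E_2nd_breakdown"] = mp_break
                v_q = v_q + vq_m
            elif opts.shell_resolved:
                dp = np.concatenate([
                    sp - np.array([sh.occupation for sh in
                                   params.element(basis.symbols[a]).shells])
                    for a, sp in enumerate(shell_pops)
                ])
                terms["E_2nd"] = 0.5 * dp @ shell_gamma @ dp
                v_sh = shell_gamma @ dp
                v_q = None  # handled per shell below
                terms["_v_shell"] = v_sh
            else:
                terms["E_2nd"] = 0.5 * dq @ gamma_mat @ dq
                v_q = v_q + gamma_mat @ dq
        if model == "dftb3":
            terms["E_3rd"] = float(np.einsum("a,ab,b->", dq * dq, big_gamma, dq) / 3.0)
            v_q = v_q + (2.0 / 3.0) * dq * (big_gamma @ dq) \
                + (big_gamma.T @ (dq * dq)) / 3.0
        if g_solv is not None:
            from .solvation import dielectric_scaling
            f_eps = dielectric_scaling(solv.epsilon, solv.alpha, solv.conductor)
            terms["E_solv"] = float(f_eps * dq @ g_solv @ dq)
            if v_q is not None:
                v_q = v_q + 2.0 * f_eps * (g_solv @ dq)
        if opts.external_potential is not None and v_q is not None:
            v_q = v_q + opts.external_potential
        if opts.constraint is not None:
            spec = opts.constraint
            for grp, lam, tgt in zip(spec.groups, spec.lambdas, spec.targets):
                pop = sum(
                    params.element(basis.symbols[a]).valence_electrons + dq[a]
                    for a in grp
                )
                terms["E_constraint"] += lam * (pop - tgt)
                if v_q is not None:
                    for a in grp:
                        v_q[a] += lam
        if v_q is None:
            # shell-resolved: expand shell potentials to a W diagonal
            v_sh = terms.pop("_v_shell")
            w = np.zeros((basis.n_basis, basis.n_basis))
            k = 0
            for i, (a, si, _) in enumerate(shell_entries):
                pass
            # map orbital -> shell entry index
            entry_index = {}
            for i, (a, si, _) in enumerate(shell_entries):
                entry_index[(a, si)] = i
            diag = np.array([
                v_sh[entry_index[(basis.atom_of[k], basis.shell_of[k])]]
                for k in range(basis.n_basis)
            ])
            if opts.external_potential is not None:
                diag = diag + opts.external_potential[basis.atom_of]
            np.fill_diagonal(w, diag)
            return w, terms
        w = _onsite_w_matrix(basis, params, v_q, v_d, v_Q)
        return w, terms

    def diagonalize(w):
        h = h0 if w is None else h0 + 0.5 * (w @ s + s @ w)
        eps, c = _solve(h, s)
        occ, fermi = fermi_fill(eps, nelec, opts.kT)
        p = density_matrix(c, occ)
        return h, eps, c, occ, fermi, p

    if model == "dftb1":
        h, eps, c, occ, fermi, p = diagonalize(None)
        dq, shell_pops = mulliken_charges(p, s, basis, params)
        terms = {"E_2nd": 0.0, "E_3rd": 0.0, "E_solv": 0.0, "E_constraint": 0.0}
        converged, n_iter = True, 1
        moments = None
    else:
        dq = np.zeros(n_atoms)
        shell_pops = [
            np.array([sh.occupation for sh in params.element(sym).shells])
            for sym in geometry.symbols
        ]
        moments = MultipoleState(
            dq=dq, dd=np.zeros((n_atoms, 3)), dQ=np.zeros((n_atoms, 3, 3))
        ) if opts.multipole else None
        mixer = _AndersonMixer(opts.mixing, opts.anderson_depth) \
            if opts.anderson else None
        converged = False
        n_iter = 0
        x_in = moments.as_vector() if opts.multipole else dq.copy()
        for n_iter in range(1, opts.max_iterations + 1):
            if opts.multipole:
                moments_in = MultipoleState.from_vector(x_in, n_atoms)
                dq = moments_in.dq
            else:
                moments_in = None
                dq = x_in
            w, terms = shift_and_energy(dq, shell_pops, moments_in)
            h, eps, c, occ, fermi, p = diagonalize(w)
            dq_out, shell_pops = mulliken_charges(p, s, basis, params)
            if opts.multipole:
                moments_out = multipole_moments(p, s, basis, params)
                x_out = moments_out.as_vector()
            else:
                x_out = dq_out
            delta = float(np.max(np.abs(x_out - x_in)))
            if delta < opts.tolerance:
                x_in = x_out
                converged = True
                break
            if mixer is not None:
                x_in = mixer.step(x_in, x_out)
            else:
                x_in = x_in + opts.mixing * (x_out - x_in)
        if opts.multipole:
            moments = MultipoleState.from_vector(x_in, n_atoms)
            dq = moments.dq
        else:
            moments = None
            dq = x_in
        # final consistent evaluation at the converged charges
        w, terms = shift_and_energy(dq, shell_pops, moments)
        h, eps, c, occ, fermi, p = diagonalize(w)
        dq_final, shell_pops = mulliken_charges(p, s, basis, params)
        if opts.multipole:
            moments = multipole_moments(p, s, basis, params)
            dq = moments.dq
        else:
            dq = dq_final

    e_band = float(np.einsum("ij,ji->", p, h0))
    terms_out = {
        "E_DFTB1": e_band,
        "E_rep": e_rep,
        "E_2nd": float(terms.get("E_2nd", 0.0)),
        "E_3rd": float(terms.get("E_3rd", 0.0)),
        "E_solv": float(terms.get("E_solv", 0.0)),
        "E_constraint": float(terms.get("E_constraint", 0.0)),
    }
    terms_out["E_total"] = sum(
        v for k, v in terms_out.items() if k.startswith("E_") and k != "E_total"
    )
    state = SCCState(
        mo_coefficients=c, mo_energies=eps, occupations=occ,
        density_matrix=p, overlap=s, hamiltonian=h, h0=h0, dq=dq,
        shell_populations=shell_pops, energy_terms=terms_out,
        converged=converged, n_iterations=n_iter, basis=basis,
        fermi_level=fermi, moments=moments,
    )
    return state


def total_energy(
    state: SCCState, params: ParameterSet, geometry: Geometry, model: str,
    options: SCCOptions | None = None,
) -> dict:
    """Recompute the energy breakdown from a state's P and charges.

    E_DFTB1 = tr(P H0); E_2nd = 1/2 sum dq gamma dq;
    E_3rd = 1/3 sum dq_A^2 dq_B Gamma_AB (dftb3); terms sum to E_total.
    """
    opts = options or SCCOptions()
    kernel = opts.kernel()
    dq = state.dq
    terms = {
        "E_DFTB1": float(np.einsum("ij,ji->", state.density_matrix, state.h0)),
        "E_rep": repulsive_energy(geometry, params),
        "E_2nd": 0.0, "E_3rd": 0.0, "E_solv": 0.0, "E_constraint": 0.0,
    }
    if model in ("dftb2", "dftb3"):
        gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
        terms["E_2nd"] = float(0.5 * dq @ gamma_mat @ dq)
        if model == "dftb3":
            terms["E_3rd"] = float(
                np.einsum("a,ab,b->", dq * dq, big_gamma, dq) / 3.0
            )
    terms["E_total"] = sum(v for k, v in terms.items() if k != "E_total")
    return terms
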