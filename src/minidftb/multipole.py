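"""Multipolar SCC electrostatics (mDFTB2 / mDFTB3).

Charge fluctuations carry, besides the Mulliken monopole dq_A, an atomic
dipole dd_A and a traceless quadrupole dQ_A obtained in the on-site
approximation: only the overlap matrix and per-element on-site multipole
integrals (D_A, Q_A, with empirical scales s_d, s_q) enter, no two-center
moment integrals.

The interaction kernels f_AB^(mn) (m, n = 0, 1, 2) are the Taylor derivatives
of the monopole kernel gamma(|r - r'|) at the atomic sites, divided by m!n!.
Since gamma depends on r - r' only, every kernel reduces to a Cartesian
derivative tensor of a radial function, assembled from analytic radial
derivatives. On-site (A = B) kernels come from the even small-R expansion of
gamma: f00 = c0, f11 = -2 c2 I, f22 = 2 c4 (3-fold delta sum), odd orders
vanish by symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CapabilityError, ConfigurationError
from .gamma import (
    GammaKernel,
    gamma_radial_derivatives,
    gamma_small_r_coeffs,
    gamma_value,
)

_DELTA = np.eye(3)


@dataclass
class MultipoleState:
    """Moments of the charge fluctuation per atom."""

    dq: np.ndarray                    # (n,)
    dd: np.ndarray                    # (n, 3)
    dQ: np.ndarray                    # (n, 3, 3), traceless symmetric

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.dq, self.dd.ravel(), self.dQ.ravel()])

    @classmethod
    def from_vector(cls, v: np.ndarray, n: int) -> "MultipoleState":
        dq = v[:n]
        dd = v[n:4 * n].reshape(n, 3)
        dQ = v[4 * n:].reshape(n, 3, 3)
        return cls(dq=dq, dd=dd, dQ=dQ)


# ------------------------------------------------------------------ moments

def multipole_moments(P, S, basis, params) -> MultipoleState:
    """On-site monopole/dipole/quadrupole fluctuation moments from P and S.

    dq is the standard Mulliken fluctuation; dd and dQ contract the
    Mulliken-symmetrized on-site density 0.5*(PS + SP)|_A with the element's
    on-site dipole / quadrupole integrals (scaled by s_d / s_q).
    """
    PS = 0.5 * (P @ S + S @ P)
    n_atoms = basis.n_atoms
    dq = np.zeros(n_atoms)
    dd = np.zeros((n_atoms, 3))
    dQ = np.zeros((n_atoms, 3, 3))
    for a in range(n_atoms):
        el = params.element(basis.symbols[a])
        sl = basis.atom_slice(a)
        rho = PS[sl, sl]
        dq[a] = np.trace(rho) - el.valence_electrons
        s_idx = basis.local_shell_orbitals(a, l=0)
        p_idx = basis.local_shell_orbitals(a, l=1)
        if p_idx is not None:
            if el.dipole_integral == 0.0 or el.quadrupole_integral == 0.0:
                raise ConfigurationError(
                    f"element {el.symbol}: on-site multipole integrals required "
                    "for the multipole model"
                )
            if s_idx is not None:
                coh = np.array([rho[s_idx[0], p_idx[k]] + rho[p_idx[k], s_idx[0]]
                                for k in range(3)])
                dd[a] = el.dipole_scale * el.dipole_integral * coh
            rho_p = rho[np.ix_(p_idx, p_idx)]
            sym = 0.5 * (rho_p + rho_p.T)
            dQ[a] = el.quadrupole_scale * el.quadrupole_integral * (
                sym - _DELTA * np.trace(sym) / 3.0
            )
    return MultipoleState(dq=dq, dd=dd, dQ=dQ)


# ------------------------------------------------------------------ kernels

def _radial_tensors(derivs: list[float], d: np.ndarray):
    """Cartesian derivative tensors T1..T4 of a radial function at vector d."""
    r = float(np.linalg.norm(d))
    n = d / r
    g1, g2, g3, g4 = derivs[1], derivs[2], derivs[3], derivs[4]
    T1 = g1 * n
    nn = np.outer(n, n)
    T2 = (g2 - g1 / r) * nn + (g1 / r) * _DELTA
    a3 = g3 - 3 * g2 / r + 3 * g1 / r ** 2
    b3 = g2 / r - g1 / r ** 2
    nnn = np.einsum("a,b,c->abc", n, n, n)
    dsum3 = (np.einsum("ab,c->abc", _DELTA, n)
             + np.einsum("ac,b->abc", _DELTA, n)
             + np.einsum("bc,a->abc", _DELTA, n))
    T3 = a3 * nnn + b3 * dsum3
    A4 = g4 - 6 * g3 / r + 15 * g2 / r ** 2 - 15 * g1 / r ** 3
    B4 = g3 / r - 3 * g2 / r ** 2 + 3 * g1 / r ** 3
    C4 = g2 / r ** 2 - g1 / r ** 3
    nnnn = np.einsum("a,b,c,d->abcd", n, n, n, n)
    dnn = (np.einsum("ab,c,d->abcd", _DELTA, n, n)
           + np.einsum("ac,b,d->abcd", _DELTA, n, n)
           + np.einsum("ad,b,c->abcd", _DELTA, n, n)
           + np.einsum("bc,a,d->abcd", _DELTA, n, n)
           + np.einsum("bd,a,c->abcd", _DELTA, n, n)
           + np.einsum("cd,a,b->abcd", _DELTA, n, n))
    dd4 = (np.einsum("ab,cd->abcd", _DELTA, _DELTA)
           + np.einsum("ac,bd->abcd", _DELTA, _DELTA)
           + np.einsum("ad,bc->abcd", _DELTA, _DELTA))
    T4 = A4 * nnnn + B4 * dnn + C4 * dd4
    return T1, T2, T3, T4


def taylor_kernel(
    u_a: float,
    u_b: float,
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    m: int,
    n: int,
    damp: float = 0.0,
) -> np.ndarray | float:
    """Kernel f_AB^(mn): (1/m!n!) d^m/dr^m d^n/dr'^n gamma at (R_A, R_B).

    Index convention: the first m Cartesian indices belong to atom A, the
    last n to atom B. Orders above 2 raise CapabilityError.
    """
    if m not in (0, 1, 2) or n not in (0, 1, 2):
        raise CapabilityError("multipole kernels support orders m, n <= 2 only")
    d = np.asarray(pos_a, dtype=float) - np.asarray(pos_b, dtype=float)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        return _onsite_kernel(u_a, u_b, m, n, damp)
    derivs = gamma_radial_derivatives(u_a, u_b, r, damp, order=m + n)
    if m + n == 0:
        return float(derivs[0])
    full = gamma_radial_derivatives(u_a, u_b, r, damp, order=4)
    T1, T2, T3, T4 = _radial_tensors(full, d)
    sign = (-1.0) ** n
    fact = {0: 1.0, 1: 1.0, 2: 2.0}
    scale = sign / (fact[m] * fact[n])
    order = m + n
    if order == 1:
        return scale * T1
    if order == 2:
        return scale * T2
    if order == 3:
        return scale * T3
    return scale * T4


def _onsite_kernel(u_a, u_b, m, n, damp):
    # the damped gamma^h coincides with gamma at R = 0 but is not smooth
    # there (the Gaussian times 1/R generates an odd term); the on-site
    # kernels are defined from the undamped even expansion
    c0, c2, c4 = gamma_small_r_coeffs(u_a, u_b, 0.0)
    order = m + n
    if order == 0:
        return c0
    if order % 2 == 1:
        shape = (3,) * order
        return np.zeros(shape)
    if order == 2:
        t2 = 2 * c2 * _DELTA
        sign = (-1.0) ** n
        fact = {0: 1.0, 1: 1.0, 2: 2.0}
        return sign / (fact[m] * fact[n]) * t2
    # order == 4 (m = n = 2)
    dd4 = (np.einsum("ab,cd->abcd", _DELTA, _DELTA)
           + np.einsum("ac,bd->abcd", _DELTA, _DELTA)
           + np.einsum("ad,bc->abcd", _DELTA, _DELTA))
    return (8 * c4 / 4.0) * dd4


@dataclass
class KernelTable:
    """All f^(mn) kernels for every ordered atom pair of a geometry."""

    f00: np.ndarray                    # (n, n)
    f01: np.ndarray                    # (n, n, 3)   monopole(A)-dipole(B)
    f11: np.ndarray                    # (n, n, 3, 3)
    f02: np.ndarray                    # (n, n, 3, 3) monopole(A)-quadrupole(B)
    f12: np.ndarray                    # (n, n, 3, 3, 3) dipole(A)-quadrupole(B)
    f22: np.ndarray                    # (n, n, 3, 3, 3, 3)


def build_kernel_table(geometry, params, kernel: GammaKernel) -> KernelTable:
    n = geometry.n_atoms
    f00 = np.zeros((n, n))
    f01 = np.zeros((n, n, 3))
    f11 = np.zeros((n, n, 3, 3))
    f02 = np.zeros((n, n, 3, 3))
    f12 = np.zeros((n, n, 3, 3, 3))
    f22 = np.zeros((n, n, 3, 3, 3, 3))
    specs = [params.element(s) for s in geometry.symbols]
    for a in range(n):
        for b in range(n):
            ea, eb = specs[a], specs[b]
            hyd = ea.hydrogen_class or eb.hydrogen_class
            damp = kernel.damping(ea.hubbard, eb.hubbard, hyd)
            pa, pb = geometry.positions[a], geometry.positions[b]
            f00[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 0, 0, damp)
            f01[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 0, 1, damp)
            f11[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 1, 1, damp)
            f02[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 0, 2, damp)
            f12[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 1, 2, damp)
            f22[a, b] = taylor_kernel(ea.hubbard, eb.hubbard, pa, pb, 2, 2, damp)
    return KernelTable(f00=f00, f01=f01, f11=f11, f02=f02, f12=f12, f22=f22)


def mdftb_energy_and_potentials(
    moments: MultipoleState, kernels: KernelTable
) -> tuple[dict, np.ndarray, np.ndarray, np.ndarray]:
    """Extended second-order energy and its derivatives w.r.t. the moments.

    Returns (breakdown, v_q, v_d, v_Q) where the breakdown maps term names
    (monopole-monopole ... quadrupole-quadrupole) to energies in hartree and
    v_* are the conjugate potentials entering the SCC Hamiltonian.
    """
    q, d, Q = moments.dq, moments.dd, moments.dQ
    e_qq = 0.5 * np.einsum("a,ab,b->", q, kernels.f00, q)
    e_qd = np.einsum("a,abx,bx->", q, kernels.f01, d)
    e_dd = 0.5 * np.einsum("ax,abxy,by->", d, kernels.f11, d)
    e_qQ = np.einsum("a,abxy,bxy->", q, kernels.f02, Q)
    e_dQ = np.einsum("ax,abxyz,byz->", d, kernels.f12, Q)
    e_QQ = 0.5 * np.einsum("axy,abxyzw,bzw->", Q, kernels.f22, Q)
    breakdown = {
        "qq": float(e_qq), "qd": float(e_qd), "dd": float(e_dd),
        "qQ": float(e_qQ), "dQ": float(e_dQ), "QQ": float(e_QQ),
        "total": float(e_qq + e_qd + e_dd + e_qQ + e_dQ + e_QQ),
    }
    v_q = (kernels.f00 @ q
           + np.einsum("abx,bx->a", kernels.f01, d)
           + np.einsum("abxy,bxy->a", kernels.f02, Q))
    v_d = (np.einsum("abxy,by->ax", kernels.f11, d)
           + np.einsum("bax,b->ax", kernels.f01, q)
           + np.einsum("abxyz,byz->ax", kernels.f12, Q))
    v_Q = (np.einsum("abxyzw,bzw->axy", kernels.f22, Q)
           + np.einsum("baxy,b->axy", kernels.f02, q)
           + np.einsum("bazxy,bz->axy", kernels.f12, d))
    return breakdown, v_q, v_d, v_Q


def mdftb_energy(moments: MultipoleState, kernels: KernelTable,
                 model: str = "mdftb2",
                 gamma_third=None) -> dict:
    """Per-order multipole electrostatic energy; mdftb3 adds the monopole
    third-order term via ``gamma_third`` = (Gamma matrix)."""
    breakdown, _, _, _ = mdftb_energy_and_potentials(moments, kernels)
    out = dict(breakdown)
    if model == "mdftb3":
        if gamma_third is None:
            raise ConfigurationError("mdftb3 requires the third-order Gamma matrix")
        q = moments.dq
        out["third_order"] = float(np.einsum("a,ab,b->", q * q, gamma_third, q) / 3.0)
        out["total"] += out["third_order"]
    elif model != "mdftb2":
        raise ConfigurationError(f"unknown multipole model {model!r}")
    return out
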