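"""Independent brute-force oracles and the named reference-record bank.

Every oracle here recomputes a quantity through a route that shares no code
with the production path it checks:

* ``gamma_quadrature`` -- double radial Gauss-Legendre quadrature of the
  two-density Coulomb integral (shell-shell angular average done in closed
  form), versus the analytic gamma;
* ``rotation_matrix_block`` -- axis-aligned Slater-Koster block rotated with
  explicit 3x3 rotation matrices, versus the direction-cosine formulas;
* ``kernel_finite_difference`` -- central differences of gamma with respect
  to Cartesian site displacements, versus the analytic Taylor kernels;
* ``scc_fixed_point`` -- plain damped fixed-point iteration of the charge
  map with its own mixing schedule, versus the production SCC loop;
* ``penalty_constrained`` -- quadratic-penalty enforcement of population
  constraints, versus the Lagrangian solver;
* ``rpa_full`` -- dense non-hermitian solve of the full 2N x 2N response
  system, versus the reduced symmetric solver;
* ``fixed_occupation_scc`` -- an independent, index-pinned unrestricted SCC
  loop, versus the maximum-overlap Delta-SCF machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .errors import ConfigurationError

# ----------------------------------------------------------------- gamma

def gamma_quadrature(u_a: float, u_b: float, r: float, n_points: int = 400) -> float:
    """Coulomb integral of two spherical exponential densities, numerically.

    Densities tau^3/(8 pi) e^(-tau r) with tau = 16 U / 5; the angular
    average of 1/|x - y| between two spherical shells is analytic, leaving a
    double radial quadrature.
    """
    ta, tb = 3.2 * u_a, 3.2 * u_b
    x, w = leggauss(n_points)
    span = 45.0 / min(ta, tb)
    rad = 0.5 * span * (x + 1.0)
    wr = 0.5 * span * w
    wa = 0.5 * ta ** 3 * rad ** 2 * np.exp(-ta * rad) * wr
    wb = 0.5 * tb ** 3 * rad ** 2 * np.exp(-tb * rad) * wr
    ra, rb = np.meshgrid(rad, rad, indexing="ij")
    lo = np.abs(r - ra)
    hi = r + ra
    m = np.clip(rb, lo, hi)
    # mean of 1/max(d, r_b) over shell directions
    phi = ((m ** 2 - lo ** 2) / (2.0 * rb) + (hi - m)) / (2.0 * r * ra)
    return float(wa @ phi @ wb)


# ------------------------------------------------------- rotation matrices

def rotation_to_axis(n: np.ndarray) -> np.ndarray:
    """A proper rotation taking the z axis onto the unit vector n."""
    n = np.asarray(n, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    c = float(z @ n)
    if np.linalg.norm(v) < 1e-14:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotation_matrix_block(table_12, table_21, l1, l2, direction, r, matrix="H"):
    """SK block via explicit rotation of the axis-aligned block."""
    rot = rotation_to_axis(direction)

    def dmat(l):
        return np.array([[1.0]]) if l == 0 else rot

    # axis-aligned block (direction +z)
    if (l1, l2) == (0, 0):
        b0 = np.array([[table_12.interpolate("sss", matrix, r)]])
    elif (l1, l2) == (0, 1):
        sps = table_12.interpolate("sps", matrix, r)
        b0 = np.array([[0.0, 0.0, sps]])
    elif (l1, l2) == (1, 0):
        sps = table_21.interpolate("sps", matrix, r)
        b0 = np.array([[0.0], [0.0], [-sps]])
    elif (l1, l2) == (1, 1):
        pps = table_12.interpolate("pps", matrix, r)
        ppp = table_12.interpolate("ppp", matrix, r)
        b0 = np.diag([ppp, ppp, pps])
    else:
        raise ConfigurationError("oracle supports s/p shells only")
    return dmat(l1) @ b0 @ dmat(l2).T


# ------------------------------------------------- kernel finite differences

def kernel_finite_difference(u_a, u_b, pos_a, pos_b, m, n, damp=0.0, h=0.05,
                             richardson=True):
    """f^(mn) by nested central differences of gamma over site displacements.

    Fourth-order five-point stencils, Richardson-extrapolated over h and h/2
    by default, keep the truncation and roundoff error of the nested
    high-order derivatives below ~1e-6 relative.
    """
    if richardson:
        f_h = kernel_finite_difference(u_a, u_b, pos_a, pos_b, m, n, damp,
                                       h, richardson=False)
        f_h2 = kernel_finite_difference(u_a, u_b, pos_a, pos_b, m, n, damp,
                                        h / 2.0, richardson=False)
        out = (16.0 * np.asarray(f_h2) - np.asarray(f_h)) / 15.0
        return float(out) if m + n == 0 else out

    from .gamma import gamma_value

    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)

    def g(da, db):
        r = np.linalg.norm((pos_a + da) - (pos_b + db))
        return gamma_value(u_a, u_b, float(r), damp)

    stencil = ((-2, 1.0 / 12.0), (-1, -8.0 / 12.0), (1, 8.0 / 12.0),
               (2, -1.0 / 12.0))

    def d_a(fun, alpha):
        e = np.zeros(3)
        e[alpha] = h
        return lambda da, db: sum(
            c * fun(da + k * e, db) for k, c in stencil) / h

    def d_b(fun, alpha):
        e = np.zeros(3)
        e[alpha] = h
        return lambda da, db: sum(
            c * fun(da, db + k * e) for k, c in stencil) / h

    fact = {0: 1.0, 1: 1.0, 2: 2.0}
    shape = (3,) * (m + n)
    if m + n == 0:
        return g(np.zeros(3), np.zeros(3))
    out = np.zeros(shape)
    for idx in np.ndindex(shape):
        fun = g
        for alpha in idx[:m]:
            fun = d_a(fun, alpha)
        for alpha in idx[m:]:
            fun = d_b(fun, alpha)
        out[idx] = fun(np.zeros(3), np.zeros(3))
    return out / (fact[m] * fact[n])


# ------------------------------------------------------------ SCC oracles

def scc_fixed_point(geometry, params, model="dftb2", mixing=0.35,
                    tol=1e-11, max_iter=800, kernel=None):
    """Damped fixed-point iteration of the charge map, alternate schedule."""
    from .gamma import GammaKernel
    from .scc import (
        build_gamma_matrices, build_h0_s, density_matrix, fermi_fill,
        mulliken_charges, n_valence_electrons, _solve,
    )

    kernel = kernel or GammaKernel(variant="gamma_h")
    h0, s, basis = build_h0_s(geometry, params)
    gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
    nelec = n_valence_electrons(geometry, params)
    n_atoms = geometry.n_atoms
    dq = np.zeros(n_atoms)
    beta = mixing
    for it in range(max_iter):
        v = gamma_mat @ dq
        if model == "dftb3":
            v = v + (2.0 / 3.0) * dq * (big_gamma @ dq) \
                + (big_gamma.T @ (dq * dq)) / 3.0
        w = np.zeros_like(h0)
        for a in range(n_atoms):
            sl = basis.atom_slice(a)
            idx = np.arange(sl.start, sl.stop)
            w[idx, idx] = v[a]
        h = h0 + 0.5 * (w @ s + s @ w)
        eps, c = _solve(h, s)
        occ, _ = fermi_fill(eps, nelec)
        p = density_matrix(c, occ)
        dq_new, _ = mulliken_charges(p, s, basis, params)
        if np.max(np.abs(dq_new - dq)) < tol:
            return dq_new, True, it + 1
        # alternating damping schedule, deliberately different from the
        # production mixer
        beta = 0.55 if it % 3 == 2 else mixing
        dq = dq + beta * (dq_new - dq)
    return dq, False, max_iter


def penalty_constrained(geometry, params, model, groups, targets,
                        weights=(1e2, 1e3, 1e4, 1e5, 1e6, 1e7),
                        tol=1e-11, max_iter=600):
    """Quadratic-penalty enforcement of group populations.

    Minimizes E + sum_i w (C_i - C_i^0)^2 for an increasing weight schedule.
    At each weight the stationarity condition v_i = 2 w (C_i[v] - C_i^0) is
    solved for the penalty shifts v_i by a damped secant/Newton iteration,
    where C_i[v] comes from a fully converged inner SCC at fixed shift.
    Returns the final charge vector and the achieved populations.
    """
    from .gamma import GammaKernel
    from .scc import (
        build_gamma_matrices, build_h0_s, density_matrix, fermi_fill,
        mulliken_charges, n_valence_electrons, _solve,
    )

    kernel = GammaKernel(variant="gamma_h")
    h0, s, basis = build_h0_s(geometry, params)
    gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
    nelec = n_valence_electrons(geometry, params)
    n_atoms = geometry.n_atoms
    q0 = np.array([params.element(sym).valence_electrons
                   for sym in geometry.symbols])
    n_g = len(groups)

    def inner_scc(v_shift):
        dq = np.zeros(n_atoms)
        for _ in range(max_iter):
            v = gamma_mat @ dq
            if model == "dftb3":
                v = v + (2.0 / 3.0) * dq * (big_gamma @ dq) \
                    + (big_gamma.T @ (dq * dq)) / 3.0
            for gi, grp in enumerate(groups):
                for a in grp:
                    v[a] += v_shift[gi]
            w = np.zeros_like(h0)
            for a in range(n_atoms):
                sl = basis.atom_slice(a)
                idx = np.arange(sl.start, sl.stop)
                w[idx, idx] = v[a]
            h = h0 + 0.5 * (w @ s + s @ w)
            eps, c = _solve(h, s)
            occ, _ = fermi_fill(eps, nelec)
            p = density_matrix(c, occ)
            dq_new, _ = mulliken_charges(p, s, basis, params)
            if np.max(np.abs(dq_new - dq)) < tol:
                return dq_new
            dq = dq + 0.2 * (dq_new - dq)
        return dq

    def group_pops(dq):
        return np.array([sum(q0[a] + dq[a] for a in grp) for grp in groups])

    v_shift = np.zeros(n_g)
    dq = inner_scc(v_shift)
    for wgt in weights:
        for _ in range(80):
            c_val = group_pops(dq)
            resid = v_shift - 2.0 * wgt * (c_val - np.asarray(targets))
            if np.max(np.abs(resid)) < max(1e-10, 1e-9 * wgt * 1e-3):
                break
            # Jacobian of the stationarity map by finite differences in v
            jac = np.eye(n_g)
            dv = 1e-4
            for gi in range(n_g):
                v_p = v_shift.copy()
                v_p[gi] += dv
                c_p = group_pops(inner_scc(v_p))
                jac[:, gi] = (np.eye(n_g)[:, gi]
                              - 2.0 * wgt * (c_p - c_val) / dv)
            try:
                step = np.linalg.solve(jac, -resid)
            except np.linalg.LinAlgError:
                step = -resid
            v_shift = v_shift + step
            dq = inner_scc(v_shift)
    pops = group_pops(dq)
    return dq, list(pops)


# ------------------------------------------------------------- RPA oracle

def rpa_full(omega_ia, k, n_states):
    """Eigenvalues of the full non-hermitian 2N x 2N response system."""
    w = np.asarray(omega_ia, dtype=float)
    a = np.diag(w) + k
    b = np.array(k, dtype=float)
    n = len(w)
    big = np.block([[a, b], [-b, -a]])
    vals = np.linalg.eigvals(big)
    pos = np.sort(vals.real[vals.real > 1e-12])
    return pos[:n_states]


# ----------------------------------------------- fixed-occupation SCC oracle

def fixed_occupation_scc(geometry, params, model, occ_up, occ_dn,
                         mixing=0.15, tol=1e-12, max_iter=3000):
    """Unrestricted SCC with occupations pinned to sorted-orbital indices.

    Independent re-implementation of the occupation-constrained loop; valid
    when no orbital crossing occurs (clean-gap fixtures).
    """
    from .gamma import GammaKernel
    from .scc import (
        build_gamma_matrices, build_h0_s, density_matrix,
        mulliken_charges, _solve,
    )

    kernel = GammaKernel(variant="gamma_h")
    h0, s, basis = build_h0_s(geometry, params)
    gamma_mat, big_gamma = build_gamma_matrices(geometry, params, kernel)
    from .scc import repulsive_energy
    n_atoms = geometry.n_atoms
    w_const = np.array([params.element(sym).spin_constant
                        for sym in geometry.symbols])
    q0 = np.array([params.element(sym).valence_electrons
                   for sym in geometry.symbols])
    dq = np.zeros(n_atoms)
    mag = np.zeros(n_atoms)
    p_up = p_dn = None
    for _ in range(max_iter):
        v_charge = np.zeros(n_atoms)
        if model in ("dftb2", "dftb3"):
            v_charge = gamma_mat @ dq
        if model == "dftb3":
            v_charge = v_charge + (2.0 / 3.0) * dq * (big_gamma @ dq) \
                + (big_gamma.T @ (dq * dq)) / 3.0
        ps = {}
        for sign, occ_list in ((1.0, occ_up), (-1.0, occ_dn)):
            v = v_charge + sign * w_const * mag
            w = np.zeros_like(h0)
            for a in range(n_atoms):
                sl = basis.atom_slice(a)
                idx = np.arange(sl.start, sl.stop)
                w[idx, idx] = v[a]
            h = h0 + 0.5 * (w @ s + s @ w)
            eps, c = _solve(h, s)
            occ = np.zeros(len(eps))
            occ[list(occ_list)] = 1.0
            ps[sign] = density_matrix(c, occ)
        dq_up, _ = mulliken_charges(ps[1.0], s, basis, params)
        dq_dn, _ = mulliken_charges(ps[-1.0], s, basis, params)
        pop_up, pop_dn = dq_up + q0, dq_dn + q0
        dq_new = pop_up + pop_dn - q0
        mag_new = pop_up - pop_dn
        delta = max(np.max(np.abs(dq_new - dq)), np.max(np.abs(mag_new - mag)))
        if delta < tol:
            dq, mag = dq_new, mag_new
            p_up, p_dn = ps[1.0], ps[-1.0]
            break
        dq = dq + mixing * (dq_new - dq)
        mag = mag + mixing * (mag_new - mag)
        p_up, p_dn = ps[1.0], ps[-1.0]
    e_band = float(np.einsum("ij,ji->", p_up + p_dn, h0))
    e2 = float(0.5 * dq @ gamma_mat @ dq) if model != "dftb1" else 0.0
    e3 = float(np.einsum("a,ab,b->", dq * dq, big_gamma, dq) / 3.0) \
        if model == "dftb3" else 0.0
    e_spin = float(0.5 * np.sum(w_const * mag ** 2))
    e_total = e_band + e2 + e3 + e_spin + repulsive_energy(geometry, params)
    return {"E_total": e_total, "dq": dq, "mag": mag}


# ------------------------------------------------------------- record bank

@dataclass
class ReferenceRecord:
    name: str
    value: object
    tolerance: float
    oracle: str


def _rec_gamma_r3() -> ReferenceRecord:
    return ReferenceRecord(
        name="gamma_R3_U4_U3",
        value=gamma_quadrature(0.4, 0.3, 3.0),
        tolerance=1e-7,
        oracle="double radial Gauss-Legendre quadrature of the two-density "
               "Coulomb integral (400 points)",
    )


def _rec_rpa_6x6() -> ReferenceRecord:
    rng = np.random.default_rng(20250606)
    w = np.sort(rng.uniform(0.2, 0.8, size=6))
    k = rng.normal(scale=0.02, size=(6, 6))
    k = 0.5 * (k + k.T)
    vals = rpa_full(w, k, 6)
    return ReferenceRecord(
        name="rpa_6x6_seed0",
        value={"omega": w, "k": k, "eigenvalues": vals},
        tolerance=1e-10,
        oracle="dense eigensolve of the full non-hermitian 2N x 2N response "
               "system (seed 20250606)",
    )


def _rec_identity_cot() -> ReferenceRecord:
    return ReferenceRecord(
        name="identity_cot",
        value=np.eye(2),
        tolerance=1e-12,
        oracle="identical determinants give an identity corresponding-orbital "
               "rotation (up to column signs)",
    )


_BANK = {
    "gamma_R3_U4_U3": _rec_gamma_r3,
    "rpa_6x6_seed0": _rec_rpa_6x6,
    "identity_cot": _rec_identity_cot,
}


def oracle_bank(name: str) -> ReferenceRecord:
    """Named reference records with oracle provenance."""
    try:
        builder = _BANK[name]
    except KeyError:
        raise KeyError(
            f"unknown oracle record {name!r}; available: {sorted(_BANK)}"
        ) from None
    return builder()
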