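"""Charge-constrained ground states.

A generalized free energy F[P, lambda] = E[P] + sum_i lambda_i (C_i[P] - C_i^0)
is made stationary: maximal in the multipliers, minimal in the density. The
constraint functionals C_i are Mulliken populations of atom groups; the
corresponding one-particle potential simply adds +lambda_i to the SCC shift
of every atom in group i.

The outer search for lambda* is a damped Newton iteration on the constraint
residual (finite-difference Jacobian), falling back to gradient ascent when
the Newton step fails to reduce the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .scc import SCCOptions, SCCState, scc_loop


@dataclass
class ConstraintSpec:
    """Population constraints on disjoint atom groups (0-based indices)."""

    groups: list[list[int]]
    targets: list[float]               # target Mulliken populations C_i^0
    lambdas: np.ndarray | None = None  # multipliers, hartree per electron
    tolerance: float = 1e-6
    max_outer: int = 60

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("constraint spec needs at least one group")
        seen: set[int] = set()
        for grp in self.groups:
            if not grp:
                raise ConfigurationError("empty constraint group")
            for a in grp:
                if a in seen:
                    raise ConfigurationError(
                        f"atom {a + 1} appears in more than one constraint group"
                    )
                seen.add(a)
        if len(self.targets) != len(self.groups):
            raise ConfigurationError("one target per group required")
        if self.lambdas is None:
            self.lambdas = np.zeros(len(self.groups))
        else:
            self.lambdas = np.asarray(self.lambdas, dtype=float)

    @property
    def n(self) -> int:
        return len(self.groups)


def constraint_value(state: SCCState, group: list[int], params) -> float:
    """Mulliken population of an atom group: C = sum_{A in group} (q_A^0 + dq_A)."""
    n_atoms = state.basis.n_atoms
    total = 0.0
    for a in group:
        if not 0 <= a < n_atoms:
            raise IndexError(f"atom index {a} outside 0..{n_atoms - 1}")
        total += params.element(state.basis.symbols[a]).valence_electrons \
            + state.dq[a]
    return float(total)


def free_energy(state: SCCState, spec: ConstraintSpec, params) -> float:
    """F = E_total(internal) + sum_i lambda_i (C_i - C_i^0)."""
    e_int = state.energy_terms["E_total"] - state.energy_terms["E_constraint"]
    f = e_int
    for grp, lam, tgt in zip(spec.groups, spec.lambdas, spec.targets):
        f += lam * (constraint_value(state, grp, params) - tgt)
    return float(f)


def _run_inner(geometry, params, model, spec, base_options):
    opts = SCCOptions(**{**base_options.__dict__}) if base_options else SCCOptions()
    opts.constraint = spec
    return scc_loop(geometry, params, model, opts)


def _residual(state: SCCState, spec: ConstraintSpec, params) -> np.ndarray:
    return np.array([
        constraint_value(state, grp, params) - tgt
        for grp, tgt in zip(spec.groups, spec.targets)
    ])


def solve_constrained(
    geometry,
    params,
    model: str,
    spec: ConstraintSpec,
    options: SCCOptions | None = None,
):
    """Outer stationarity search for the multipliers.

    Returns (state, info) where info records ``converged``, the multiplier
    vector ``lambdas``, the residuals, and the free-energy trajectory.
    Unreachable targets surface as ``converged=False`` with the residual,
    not as an exception.
    """
    spec = ConstraintSpec(
        groups=spec.groups, targets=list(spec.targets),
        lambdas=np.array(spec.lambdas, dtype=float),
        tolerance=spec.tolerance, max_outer=spec.max_outer,
    )
    base = options or SCCOptions()
    lam = spec.lambdas.copy()
    trajectory = []
    state = _run_inner(geometry, params, model, spec, base)
    res = _residual(state, spec, params)
    trajectory.append({"lambda": lam.copy(), "residual": res.copy(),
                       "F": free_energy(state, spec, params)})
    h_fd = 1e-4
    for _ in range(spec.max_outer):
        if np.max(np.abs(res)) < spec.tolerance:
            break
        # finite-difference Jacobian dC/dlambda (typically negative definite)
        jac = np.zeros((spec.n, spec.n))
        for k in range(spec.n):
            pert = spec.lambdas.copy()
            pert[k] += h_fd
            spec_p = ConstraintSpec(
                groups=spec.groups, targets=list(spec.targets), lambdas=pert,
                tolerance=spec.tolerance, max_outer=spec.max_outer,
            )
            st_p = _run_inner(geometry, params, model, spec_p, base)
            jac[:, k] = (_residual(st_p, spec_p, params) - res) / h_fd
        try:
            step = np.linalg.solve(jac, -res)
        except np.linalg.LinAlgError:
            step = res * 1.0  # gradient ascent on F (dF/dlambda = residual)
        # damped line search on the residual norm
        scale = 1.0
        best = None
        for _ in range(8):
            lam_try = spec.lambdas + scale * step
            spec_try = ConstraintSpec(
                groups=spec.groups, targets=list(spec.targets), lambdas=lam_try,
                tolerance=spec.tolerance, max_outer=spec.max_outer,
            )
            st_try = _run_inner(geometry, params, model, spec_try, base)
            res_try = _residual(st_try, spec_try, params)
            if np.linalg.norm(res_try) < np.linalg.norm(res) or best is None:
                best = (spec_try, st_try, res_try)
                if np.linalg.norm(res_try) < np.linalg.norm(res):
                    break
            scale *= 0.5
        spec, state, res = best
        trajectory.append({"lambda": spec.lambdas.copy(), "residual": res.copy(),
                           "F": free_energy(state, spec, params)})
    converged = bool(np.max(np.abs(res)) < spec.tolerance)
    info = {
        "converged": converged,
        "lambdas": spec.lambdas.copy(),
        "residual": res.copy(),
        "trajectory": trajectory,
        "F": free_energy(state, spec, params),
    }
    state.lambdas = spec.lambdas.copy()
    return state, info
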