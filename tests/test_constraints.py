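"""Charge-constrained ground states via the Lagrangian free energy."""

import numpy as np
import pytest

import minidftb as md
from minidftb.constraints import (
    ConstraintSpec,
    constraint_value,
    free_energy,
    solve_constrained,
)
from minidftb.errors import ConfigurationError
from minidftb.oracles import penalty_constrained
from minidftb.scc import SCCOptions, scc_loop


def test_group_of_all_atoms_closes_to_total_electron_count(suite, params):
    geom = suite.geometry("XY2")
    state = scc_loop(geom, params, "dftb2")
    total = constraint_value(state, [0, 1, 2], params)
    assert total == pytest.approx(8.0, abs=1e-9)


def test_symmetric_dimer_groups_have_equal_populations(suite, params):
    state = scc_loop(suite.geometry("X2"), params, "dftb2")
    c0 = constraint_value(state, [0], params)
    c1 = constraint_value(state, [1], params)
    assert c0 == pytest.approx(c1, abs=1e-10)


def test_constraint_value_matches_per_atom_mulliken_sum(suite, params):
    geom = suite.geometry("XY2")
    state = scc_loop(geom, params, "dftb3")
    # independent recomputation from P and S
    diag = np.einsum("ij,ji->i", state.density_matrix, state.overlap)
    pops = np.zeros(geom.n_atoms)
    for k in range(state.basis.n_basis):
        pops[state.basis.atom_of[k]] += diag[k]
    group = [0, 2]
    assert constraint_value(state, group, params) == pytest.approx(
        sum(pops[a] for a in group), abs=1e-12
    )


def test_invalid_atom_index_raises(suite, params):
    state = scc_loop(suite.geometry("X2"), params, "dftb2")
    with pytest.raises(IndexError):
        constraint_value(state, [5], params)


def test_overlapping_groups_rejected():
    with pytest.raises(ConfigurationError, match="more than one"):
        ConstraintSpec(groups=[[0, 1], [1, 2]], targets=[1.0, 1.0])


def test_zero_multiplier_free_energy_equals_total_energy(suite, params):
    geom = suite.geometry("XY")
    spec = ConstraintSpec(groups=[[0]], targets=[1.3])
    state = scc_loop(geom, params, "dftb2")
    assert free_energy(state, spec, params) == pytest.approx(
        state.e_total, abs=1e-12
    )


def test_satisfied_constraint_free_energy_equals_energy_for_any_lambda(
    suite, params
):
    geom = suite.geometry("XY")
    state = scc_loop(geom, params, "dftb2")
    c_now = constraint_value(state, [0], params)
    for lam in (-0.5, 0.2, 1.0):
        spec = ConstraintSpec(groups=[[0]], targets=[c_now],
                              lambdas=np.array([lam]))
        assert free_energy(state, spec, params) == pytest.approx(
            state.e_total, abs=1e-10
        )


def test_already_satisfied_target_gives_zero_multiplier(suite, params):
    geom = suite.geometry("XY")
    free_state = scc_loop(geom, params, "dftb2", SCCOptions(tolerance=1e-12))
    target = constraint_value(free_state, [0], params)
    spec = ConstraintSpec(groups=[[0]], targets=[target])
    state, info = solve_constrained(geom, params, "dftb2", spec,
                                    SCCOptions(tolerance=1e-12))
    assert info["converged"]
    assert abs(info["lambdas"][0]) < 1e-6
    assert info["F"] == pytest.approx(
        free_state.e_total, abs=1e-8
    )


def test_df_dlambda_is_the_constraint_residual(suite, params):
    """Central-difference dF/dlambda (inner SCC re-converged) = C - C0."""
    geom = suite.geometry("XY")
    target = 1.4
    opts = SCCOptions(tolerance=1e-12)
    lam0, h = -0.1, 1e-4
    vals = {}
    for lam in (lam0 - h, lam0, lam0 + h):
        spec = ConstraintSpec(groups=[[0]], targets=[target],
                              lambdas=np.array([lam]))
        st = scc_loop(geom, params, "dftb2",
                      SCCOptions(tolerance=1e-12, constraint=spec))
        vals[lam] = (free_energy(st, spec, params),
                     constraint_value(st, [0], params))
    fd = (vals[lam0 + h][0] - vals[lam0 - h][0]) / (2 * h)
    residual = vals[lam0][1] - target
    assert fd == pytest.approx(residual, abs=1e-6)


def test_forced_half_electron_transfer_hits_target(suite, params):
    geom = suite.geometry("XY")
    free_state = scc_loop(geom, params, "dftb2", SCCOptions(tolerance=1e-12))
    c_free = constraint_value(free_state, [0], params)
    target = c_free + 0.5
    spec = ConstraintSpec(groups=[[0]], targets=[target])
    state, info = solve_constrained(geom, params, "dftb2", spec,
                                    SCCOptions(tolerance=1e-12))
    assert info["converged"]
    assert constraint_value(state, [0], params) == pytest.approx(
        target, abs=1e-6
    )
    # quadratic-penalty oracle reaches the same charge distribution
    dq_pen, pops = penalty_constrained(geom, params, "dftb2", [[0]], [target])
    assert pops[0] == pytest.approx(target, abs=1e-6)
    assert np.max(np.abs(state.dq - dq_pen)) < 1e-6


def test_free_energy_is_maximal_in_lambda(suite, params):
    geom = suite.geometry("XY")
    target = 1.6
    spec = ConstraintSpec(groups=[[0]], targets=[target])
    state, info = solve_constrained(geom, params, "dftb2", spec,
                                    SCCOptions(tolerance=1e-12))
    f_star = info["F"]
    for delta in (-0.01, 0.01):
        probe = ConstraintSpec(
            groups=[[0]], targets=[target],
            lambdas=info["lambdas"] + delta,
        )
        st = scc_loop(geom, params, "dftb2",
                      SCCOptions(tolerance=1e-12, constraint=probe))
        assert free_energy(st, probe, params) <= f_star + 1e-9


def test_constrained_energy_exceeds_ground_state_convexly(suite, params):
    geom = suite.geometry("XY")
    opts = SCCOptions(tolerance=1e-11)
    free_state = scc_loop(geom, params, "dftb2", opts)
    e_free = free_state.e_total
    c_free = constraint_value(free_state, [0], params)
    energies = []
    for shift in (-0.4, -0.2, 0.0, 0.2, 0.4):
        spec = ConstraintSpec(groups=[[0]], targets=[c_free + shift])
        state, info = solve_constrained(geom, params, "dftb2", spec, opts)
        assert info["converged"]
        e_int = state.energy_terms["E_total"] - state.energy_terms["E_constraint"]
        energies.append(e_int)
        assert e_int >= e_free - 1e-9
    # convex profile: internal energy grows away from the free minimum
    assert energies[0] > energies[1] > energies[2] - 1e-12
    assert energies[4] > energies[3] > energies[2] - 1e-12


def test_target_to_energy_map_is_continuous(suite, params):
    geom = suite.geometry("XY")
    opts = SCCOptions(tolerance=1e-11)
    base = 1.5
    e_vals = []
    for dt in (0.0, 1e-3, 2e-3):
        spec = ConstraintSpec(groups=[[0]], targets=[base + dt])
        state, info = solve_constrained(geom, params, "dftb2", spec, opts)
        e_vals.append(state.energy_terms["E_total"]
                      - state.energy_terms["E_constraint"])
    assert abs(e_vals[1] - e_vals[0]) < 5e-3
    assert abs(e_vals[2] - e_vals[1]) < 5e-3
    assert abs(e_vals[2] - e_vals[1]) == pytest.approx(
        abs(e_vals[1] - e_vals[0]), abs=1e-3
    )


def test_unreachable_target_flagged_not_raised(suite, params):
    geom = suite.geometry("X2")
    # a one-atom group cannot hold 5 electrons in a 2-orbital dimer
    spec = ConstraintSpec(groups=[[0]], targets=[5.0], max_outer=8)
    state, info = solve_constrained(geom, params, "dftb2", spec)
    assert not info["converged"]
    assert np.max(np.abs(info["residual"])) > 0.1
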