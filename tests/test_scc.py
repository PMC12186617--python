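"""SCC engine: H0/S assembly, occupations, charges, energies, fixed point."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import minidftb as md
from minidftb.errors import CapacityError, ConfigurationError
from minidftb.geometry import Geometry
from minidftb.oracles import scc_fixed_point
from minidftb.scc import (
    SCCOptions,
    build_gamma_matrices,
    build_h0_s,
    density_matrix,
    fermi_fill,
    mulliken_charges,
    n_valence_electrons,
    scc_loop,
    total_energy,
)

EVEN_FIXTURES = ["X2", "XY", "XY2", "X4"]
ALL_FIXTURES = ["X2", "XY", "XY2", "X3", "X4"]


# ------------------------------------------------------------ H0 and S

def test_single_atom_h0_is_diagonal_onsite(params):
    geom = Geometry(["Y"], [[0.0, 0.0, 0.0]])
    h0, s, basis = build_h0_s(geom, params)
    el = params.element("Y")
    expected = [el.shells[0].energy] + [el.shells[1].energy] * 3
    assert np.allclose(np.diag(h0), expected)
    assert np.allclose(h0, np.diag(np.diag(h0)))
    assert np.allclose(s, np.eye(4))


def test_homonuclear_s_dimer_matrices_are_table_lookups(params):
    r = 2.0
    geom = Geometry(["X", "X"], [[0, 0, 0], [0, 0, r]])
    h0, s, _ = build_h0_s(geom, params)
    t = params.tables[("X", "X")]
    assert h0[0, 1] == pytest.approx(t.interpolate("sss", "H", r), abs=1e-14)
    assert s[0, 1] == pytest.approx(t.interpolate("sss", "S", r), abs=1e-14)
    assert np.allclose(h0, h0.T) and np.allclose(s, s.T)


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_overlap_positive_definite_on_fixtures(suite, params, name):
    _, s, _ = build_h0_s(suite.geometry(name), params)
    assert np.linalg.eigvalsh(s).min() > 0.0


def test_missing_pair_table_names_the_pair(params):
    import copy

    broken = copy.deepcopy(params)
    del broken.tables[("X", "Y")]
    geom = Geometry(["X", "Y"], [[0, 0, 0], [0, 0, 2.0]])
    with pytest.raises(ConfigurationError, match="X-Y"):
        build_h0_s(geom, broken)


# ------------------------------------------------------------ occupations

def test_aufbau_integer_occupations_for_gapped_spectrum():
    occ, fermi = fermi_fill(np.array([-1.0, -0.5, 0.2, 0.9]), 4.0)
    assert np.allclose(occ, [2, 2, 0, 0])
    assert fermi == pytest.approx(-0.5)


def test_degenerate_homo_shares_electrons_equally():
    occ, _ = fermi_fill(np.array([-1.0, -0.3, -0.3, 0.5]), 4.0)
    assert np.allclose(occ, [2, 1, 1, 0])


def test_fermi_occupations_match_bisection_oracle():
    e = np.array([-0.9, -0.2, 0.1, 0.4])
    n_elec, kT = 4.0, 0.01
    occ, mu = fermi_fill(e, n_elec, kT)
    # independent oracle: brentq on the counting function
    from scipy.optimize import brentq

    mu_ref = brentq(
        lambda m: np.sum(2.0 / (1.0 + np.exp((e - m) / kT))) - n_elec,
        -2.0, 2.0, xtol=1e-15,
    )
    occ_ref = 2.0 / (1.0 + np.exp((e - mu_ref) / kT))
    assert np.max(np.abs(occ - occ_ref)) < 1e-10
    assert occ.sum() == pytest.approx(n_elec, abs=1e-12)


@settings(deadline=None, max_examples=30)
@given(
    energies=st.lists(st.floats(-2, 2), min_size=2, max_size=12),
    filled=st.floats(0.0, 1.0),
    kt=st.sampled_from([0.0, 0.005, 0.05]),
)
def test_occupations_conserve_electron_count_and_bounds(energies, filled, kt):
    e = np.array(energies)
    n_elec = filled * 2 * len(e)
    occ, _ = fermi_fill(e, n_elec, kt)
    assert occ.sum() == pytest.approx(n_elec, abs=1e-10)
    assert np.all(occ > -1e-12) and np.all(occ < 2 + 1e-12)


def test_overfilled_spectrum_raises():
    with pytest.raises(CapacityError):
        fermi_fill(np.array([0.0, 1.0]), 5.0)


# ------------------------------------------------------------ Mulliken

def test_neutral_free_atom_has_zero_fluctuation(params):
    geom = Geometry(["Y"], [[0, 0, 0]])
    st_atom = scc_loop(geom, params, "dftb2")
    assert np.max(np.abs(st_atom.dq)) < 1e-12


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_charge_conservation(suite, params, name):
    geom = suite.geometry(name)
    for model in ("dftb2", "dftb3"):
        state = scc_loop(geom, params, model)
        assert state.converged
        assert state.dq.sum() == pytest.approx(-geom.net_charge, abs=1e-9)
        # conservation identity against the density matrix
        trace_ps = np.einsum("ij,ji->", state.density_matrix, state.overlap)
        assert trace_ps == pytest.approx(
            n_valence_electrons(geom, params), abs=1e-9
        )


def test_symmetric_dimer_charges_vanish(suite, params):
    state = scc_loop(suite.geometry("X2"), params, "dftb2")
    assert np.max(np.abs(state.dq)) < 1e-10
    assert abs(state.energy_terms["E_2nd"]) < 1e-20


# ------------------------------------------------------------ SCC loop

def test_single_atom_energy_is_first_order_only(params):
    geom = Geometry(["Y"], [[0, 0, 0]])
    for model in ("dftb1", "dftb2", "dftb3"):
        state = scc_loop(geom, params, model)
        assert state.energy_terms["E_2nd"] == 0.0
        assert state.energy_terms["E_3rd"] == 0.0
        assert state.e_total == pytest.approx(
            state.energy_terms["E_DFTB1"], abs=1e-12
        )


def test_xy_fixed_point_matches_independent_oracle(suite, params):
    geom = suite.geometry("XY")
    for model in ("dftb2", "dftb3"):
        state = scc_loop(geom, params, model,
                         SCCOptions(tolerance=1e-11))
        dq_ref, ok, _ = scc_fixed_point(geom, params, model)
        assert ok
        assert np.max(np.abs(state.dq - dq_ref)) < 1e-8


def test_anderson_mixing_reaches_the_same_fixed_point(suite, params):
    geom = suite.geometry("XY2")
    plain = scc_loop(geom, params, "dftb3", SCCOptions(tolerance=1e-11))
    accel = scc_loop(geom, params, "dftb3",
                     SCCOptions(tolerance=1e-11, anderson=True))
    assert accel.converged
    assert np.max(np.abs(plain.dq - accel.dq)) < 1e-8
    assert accel.n_iterations <= plain.n_iterations


def test_dftb3_with_zero_hubbard_derivative_equals_dftb2(suite, params):
    import copy

    p0 = copy.deepcopy(params)
    for el in p0.elements.values():
        el.hubbard_derivative = [0.0] * len(el.hubbard_derivative)
    geom = suite.geometry("XY2")
    e2 = scc_loop(geom, p0, "dftb2", SCCOptions(tolerance=1e-12)).e_total
    e3 = scc_loop(geom, p0, "dftb3", SCCOptions(tolerance=1e-12)).e_total
    assert e3 == pytest.approx(e2, abs=1e-12)


def test_dftb2_with_zero_gamma_equals_dftb1(suite, params, monkeypatch):
    geom = suite.geometry("XY2")
    e1 = scc_loop(geom, params, "dftb1").e_total

    import minidftb.scc as scc_mod

    def zero_gamma(geometry, prm, kernel):
        n = geometry.n_atoms
        return np.zeros((n, n)), np.zeros((n, n))

    monkeypatch.setattr(scc_mod, "build_gamma_matrices", zero_gamma)
    e2 = scc_loop(geom, params, "dftb2").e_total
    assert e2 == pytest.approx(e1, abs=1e-12)


def test_non_convergence_is_flagged_not_raised(suite, params):
    state = scc_loop(suite.geometry("XY2"), params, "dftb2",
                     SCCOptions(max_iterations=2))
    assert not state.converged


def test_shell_resolved_conserves_charge_and_differs_slightly(suite, params):
    geom = suite.geometry("XY2")
    atomic = scc_loop(geom, params, "dftb2")
    shellr = scc_loop(geom, params, "dftb2", SCCOptions(shell_resolved=True))
    assert shellr.converged
    assert shellr.dq.sum() == pytest.approx(0.0, abs=1e-9)
    assert shellr.e_total != atomic.e_total  # distinct electrostatic model
    assert abs(shellr.e_total - atomic.e_total) < 0.05


# ------------------------------------------------------------ energies

def test_second_order_energy_term_by_term(params):
    gamma_mat = np.array([[0.42, 0.2], [0.2, 0.36]])
    dq = np.array([0.1, -0.1])
    expected = 0.5 * (
        dq[0] ** 2 * gamma_mat[0, 0] + dq[1] ** 2 * gamma_mat[1, 1]
        + 2 * dq[0] * dq[1] * gamma_mat[0, 1]
    )
    assert 0.5 * dq @ gamma_mat @ dq == pytest.approx(expected, abs=1e-15)


def test_repulsive_energy_is_pairwise_additive(suite, params):
    from minidftb.scc import repulsive_energy
    from minidftb.skf import evaluate_repulsive

    geom = suite.geometry("X3")
    pair_sum = sum(
        evaluate_repulsive(params.tables[("X", "X")], geom.distance(i, j))
        for i in range(3) for j in range(i + 1, 3)
    )
    assert repulsive_energy(geom, params) == pytest.approx(pair_sum, abs=1e-15)


def test_total_energy_recomputation_matches_loop(suite, params):
    geom = suite.geometry("XY2")
    state = scc_loop(geom, params, "dftb3", SCCOptions(tolerance=1e-11))
    terms = total_energy(state, params, geom, "dftb3")
    for key in ("E_DFTB1", "E_rep", "E_2nd", "E_3rd", "E_total"):
        assert terms[key] == pytest.approx(
            state.energy_terms[key], abs=1e-9
        )


def test_energy_terms_sum_to_total(suite, params):
    state = scc_loop(suite.geometry("XY"), params, "dftb3")
    t = state.energy_terms
    assert t["E_total"] == pytest.approx(
        t["E_DFTB1"] + t["E_rep"] + t["E_2nd"] + t["E_3rd"]
        + t["E_solv"] + t["E_constraint"], abs=1e-13
    )


# ------------------------------------------------------------ invariants

@pytest.mark.parametrize("name", EVEN_FIXTURES)
def test_density_matrix_idempotency_closed_shell(suite, params, name):
    state = scc_loop(suite.geometry(name), params, "dftb2",
                     SCCOptions(tolerance=1e-11))
    p, s = state.density_matrix, state.overlap
    assert np.max(np.abs(p @ s @ p - 2 * p)) < 1e-8


def test_converged_energy_is_stationary_under_charge_perturbation(suite, params):
    geom = suite.geometry("XY")
    opts = SCCOptions(tolerance=1e-12)
    state = scc_loop(geom, params, "dftb2", opts)
    gamma_mat, _ = build_gamma_matrices(geom, params, opts.kernel())
    h0, s, basis = build_h0_s(geom, params)
    nelec = n_valence_electrons(geom, params)
    from minidftb.scc import _solve, repulsive_energy

    def functional(dq_in):
        v = gamma_mat @ dq_in
        w = np.zeros_like(h0)
        for a in range(geom.n_atoms):
            sl = basis.atom_slice(a)
            idx = np.arange(sl.start, sl.stop)
            w[idx, idx] = v[a]
        h = h0 + 0.5 * (w @ s + s @ w)
        eps, c = _solve(h, s)
        occ, _ = fermi_fill(eps, nelec)
        p = density_matrix(c, occ)
        dq_out, _ = mulliken_charges(p, s, basis, params)
        return (np.einsum("ij,ji->", p, h0)
                + 0.5 * dq_out @ gamma_mat @ dq_out
                + repulsive_energy(geom, params))

    e0 = functional(state.dq)
    for a in range(geom.n_atoms):
        for sign in (+1, -1):
            pert = state.dq.copy()
            pert[a] += sign * 1e-4
            assert functional(pert) >= e0 - 1e-7


def test_dimer_energy_curve_is_smooth(params):
    energies = []
    rs = np.arange(1.8, 2.21, 1e-3)[:5]
    for r in rs:
        geom = Geometry(["X", "Y"], [[0, 0, 0], [0, 0, r]], net_charge=-1.0)
        energies.append(scc_loop(geom, params, "dftb2",
                                 SCCOptions(tolerance=1e-11)).e_total)
    h = 1e-3
    curv = [(energies[i + 1] + energies[i - 1] - 2 * energies[i]) / h ** 2
            for i in range(1, len(energies) - 1)]
    assert np.all(np.abs(curv) < 10.0)
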