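"""Multipolar electrostatics: moments, Taylor kernels, extended energy."""

import copy

import numpy as np
import pytest

import minidftb as md
from minidftb.errors import CapabilityError, ConfigurationError
from minidftb.geometry import Geometry
from minidftb.multipole import (
    KernelTable,
    MultipoleState,
    build_kernel_table,
    mdftb_energy,
    mdftb_energy_and_potentials,
    multipole_moments,
    taylor_kernel,
)
from minidftb.oracles import kernel_finite_difference
from minidftb.scc import SCCOptions, build_gamma_matrices, build_h0_s, scc_loop


# ------------------------------------------------------------- kernels

def test_zeroth_kernel_is_gamma(params):
    from minidftb.gamma import gamma_value

    pa, pb = np.zeros(3), np.array([0.0, 0.0, 3.0])
    assert taylor_kernel(0.42, 0.36, pa, pb, 0, 0) == pytest.approx(
        gamma_value(0.42, 0.36, 3.0), abs=1e-14
    )


@pytest.mark.parametrize("mn", [(0, 1), (1, 0), (1, 1), (0, 2), (2, 0),
                                (1, 2), (2, 1), (2, 2)])
@pytest.mark.parametrize("sep", [2.0, 2.5, 3.0, 4.5, 7.0])
def test_kernels_match_finite_differences(mn, sep):
    m, n = mn
    pa = np.zeros(3)
    pb = np.array([0.8, -0.3, 1.0])
    pb *= sep / np.linalg.norm(pb)
    got = taylor_kernel(0.42, 0.36, pa, pb, m, n, damp=0.05)
    ref = kernel_finite_difference(0.42, 0.36, pa, pb, m, n, damp=0.05)
    scale = max(np.max(np.abs(ref)), 1e-14)
    assert np.max(np.abs(np.asarray(got) - ref)) / scale < 1e-6


def test_f01_finite_difference_small_step():
    """First-order kernel against plain central differences with step 1e-4."""
    from minidftb.gamma import gamma_value

    pa, pb = np.zeros(3), np.array([3.0, 0.0, 0.0])
    got = taylor_kernel(0.4, 0.3, pa, pb, 0, 1)
    h = 1e-4
    for alpha in range(3):
        e = np.zeros(3)
        e[alpha] = h
        fd = (gamma_value(0.4, 0.3, float(np.linalg.norm(pa - (pb + e))))
              - gamma_value(0.4, 0.3, float(np.linalg.norm(pa - (pb - e))))) / (2 * h)
        assert got[alpha] == pytest.approx(fd, rel=1e-6, abs=1e-12)


def test_far_field_dipole_dipole_tensor():
    r = 40.0
    pa, pb = np.zeros(3), np.array([0.0, 0.0, r])
    f11 = taylor_kernel(0.42, 0.36, pa, pb, 1, 1)
    n = (pa - pb) / r
    point_dipole = -(3.0 * np.outer(n, n) - np.eye(3)) / r ** 3
    assert np.max(np.abs(f11 - point_dipole)) < 1e-6


def test_order_above_two_is_capability_error():
    with pytest.raises(CapabilityError):
        taylor_kernel(0.4, 0.4, np.zeros(3), np.array([1.0, 0, 0]), 3, 0)


def test_kernel_slot_symmetry(suite, params):
    """f_AB^(mn) equals the transposed f_BA^(nm) slot-for-slot."""
    kernels = build_kernel_table(suite.geometry("XY2"), params,
                                 SCCOptions().kernel())
    assert np.allclose(kernels.f00, kernels.f00.T, atol=1e-13)
    assert np.allclose(kernels.f01[0, 1], -kernels.f01[1, 0], atol=1e-13)
    assert np.allclose(kernels.f11[0, 1], kernels.f11[1, 0].T, atol=1e-13)


# ------------------------------------------------------------- moments

def test_closed_s_shell_atom_has_no_higher_moments(params):
    geom = Geometry(["Y"], [[0, 0, 0]])
    state = scc_loop(geom, params, "dftb2")
    moments = multipole_moments(state.density_matrix, state.overlap,
                                state.basis, params)
    assert np.max(np.abs(moments.dd)) < 1e-12
    assert np.max(np.abs(moments.dQ)) < 1e-12


def test_single_atom_sp_coherence_gives_closed_form_dipole(params):
    geom = Geometry(["Y"], [[0, 0, 0]])
    h0, s, basis = build_h0_s(geom, params)
    el = params.element("Y")
    # density matrix with an explicit s-p_z coherence
    p = np.zeros((4, 4))
    p[0, 0] = 2.0
    coh = 0.3
    p[0, 3] = p[3, 0] = coh
    moments = multipole_moments(p, s, basis, params)
    # on-site overlap is the identity, so the symmetrized coherence is 2*coh
    expected = 2.0 * coh * el.dipole_scale * el.dipole_integral
    assert moments.dd[0] == pytest.approx([0.0, 0.0, expected], abs=1e-13)
    # direct orbital-pair summation oracle
    direct = sum(
        p[i, j] * el.dipole_integral
        for i, j in [(0, 3), (3, 0)]
    )
    assert moments.dd[0][2] == pytest.approx(direct, abs=1e-13)


def test_quadrupoles_are_traceless(suite, params):
    state = scc_loop(suite.geometry("XY2"), params, "dftb2",
                     SCCOptions(multipole=True))
    for q in state.moments.dQ:
        assert abs(np.trace(q)) < 1e-12
        assert np.allclose(q, q.T, atol=1e-12)


# ------------------------------------------------------------- energies

def test_zero_higher_moments_reduce_to_monopole_second_order(suite, params):
    geom = suite.geometry("XY2")
    kernels = build_kernel_table(geom, params, SCCOptions().kernel())
    gamma_mat, _ = build_gamma_matrices(geom, params, SCCOptions().kernel())
    dq = np.array([0.5, -0.25, -0.25])
    n = geom.n_atoms
    moments = MultipoleState(dq=dq, dd=np.zeros((n, 3)), dQ=np.zeros((n, 3, 3)))
    breakdown = mdftb_energy(moments, kernels)
    assert breakdown["total"] == pytest.approx(
        0.5 * dq @ gamma_mat @ dq, abs=1e-13
    )
    for key in ("qd", "dd", "qQ", "dQ", "QQ"):
        assert breakdown[key] == 0.0


def test_antiparallel_dipoles_match_direct_pair_sum(params):
    r = 10.0
    geom = Geometry(["Y", "Y"], [[0, 0, 0], [0, 0, r]])
    kernels = build_kernel_table(geom, params, SCCOptions().kernel())
    dd = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    moments = MultipoleState(dq=np.zeros(2), dd=dd, dQ=np.zeros((2, 3, 3)))
    breakdown = mdftb_energy(moments, kernels)
    # direct summation oracle over ordered pairs, including on-site terms
    direct = 0.5 * sum(
        dd[a] @ kernels.f11[a, b] @ dd[b]
        for a in range(2) for b in range(2)
    )
    assert breakdown["total"] == pytest.approx(direct, abs=1e-14)
    # at 10 bohr the interaction approaches the antiparallel point-dipole
    # value, up to the residual exponential screening (few percent)
    inter = dd[0] @ kernels.f11[0, 1] @ dd[1]
    assert inter == pytest.approx(2.0 / r ** 3, rel=0.05)


def test_energy_invariant_under_atom_relabeling(params):
    geom = Geometry(["Y", "Y"], [[0, 0, 0], [0.5, 0.7, 2.0]])
    kernels = build_kernel_table(geom, params, SCCOptions().kernel())
    rng = np.random.default_rng(20250606)
    dq = rng.normal(size=2)
    dd = rng.normal(size=(2, 3))
    qraw = rng.normal(size=(2, 3, 3))
    dQ = np.array([0.5 * (q + q.T) - np.eye(3) * np.trace(q) / 3 for q in qraw])
    e1 = mdftb_energy(MultipoleState(dq, dd, dQ), kernels)["total"]
    geom2 = Geometry(["Y", "Y"], [[0.5, 0.7, 2.0], [0, 0, 0]])
    kernels2 = build_kernel_table(geom2, params, SCCOptions().kernel())
    e2 = mdftb_energy(
        MultipoleState(dq[::-1], dd[::-1], dQ[::-1]), kernels2
    )["total"]
    assert e1 == pytest.approx(e2, abs=1e-12)


def test_scaling_switch_off_recovers_plain_dftb2(suite, params):
    p0 = copy.deepcopy(params)
    for el in p0.elements.values():
        el.dipole_scale = 0.0
        el.quadrupole_scale = 0.0
    geom = suite.geometry("XY2")
    with_mp = scc_loop(geom, p0, "dftb2", SCCOptions(multipole=True,
                                                     tolerance=1e-11))
    plain = scc_loop(geom, params, "dftb2", SCCOptions(tolerance=1e-11))
    assert with_mp.e_total == pytest.approx(plain.e_total, abs=1e-10)
    assert np.max(np.abs(with_mp.moments.dd)) < 1e-12


def test_mdftb3_with_zero_hubbard_derivative_equals_mdftb2(suite, params):
    p0 = copy.deepcopy(params)
    for el in p0.elements.values():
        el.hubbard_derivative = [0.0] * len(el.hubbard_derivative)
    geom = suite.geometry("XY2")
    e2 = scc_loop(geom, p0, "dftb2",
                  SCCOptions(multipole=True, tolerance=1e-12)).e_total
    e3 = scc_loop(geom, p0, "dftb3",
                  SCCOptions(multipole=True, tolerance=1e-12)).e_total
    assert e3 == pytest.approx(e2, abs=1e-12)


def test_multipole_scc_conserves_charge_and_rotates_invariantly(suite, params):
    geom = suite.geometry("XY2")
    st1 = scc_loop(geom, params, "dftb2",
                   SCCOptions(multipole=True, tolerance=1e-11))
    assert st1.converged
    assert st1.dq.sum() == pytest.approx(0.0, abs=1e-9)
    # rigid rotation of the geometry leaves the energy invariant
    from minidftb.oracles import rotation_to_axis

    rot = rotation_to_axis(np.array([1.0, 2.0, 2.0]) / 3.0)
    st2 = scc_loop(geom.rotated(rot), params, "dftb2",
                   SCCOptions(multipole=True, tolerance=1e-11))
    assert st2.e_total == pytest.approx(st1.e_total, abs=1e-10)


def test_multipole_potentials_match_energy_finite_differences(suite, params):
    """The SCC back-coupling: dE/dP against finite differences of E[P]."""
    geom = suite.geometry("XY2")
    opts = SCCOptions(multipole=True, tolerance=1e-11)
    state = scc_loop(geom, params, "dftb2", opts)
    kernels = build_kernel_table(geom, params, opts.kernel())
    basis = state.basis
    s = state.overlap

    def electrostatic_energy(p):
        moments = multipole_moments(p, s, basis, params)
        return mdftb_energy_and_potentials(moments, kernels)[0]["total"]

    moments = multipole_moments(state.density_matrix, s, basis, params)
    _, v_q, v_d, v_Q = mdftb_energy_and_potentials(moments, kernels)
    from minidftb.scc import _onsite_w_matrix

    w = _onsite_w_matrix(basis, params, v_q, v_d, v_Q)
    h1 = 0.5 * (w @ s + s @ w)
    h = 1e-6
    rng = np.random.default_rng(4)
    for _ in range(6):
        i, j = rng.integers(0, basis.n_basis, size=2)
        dp = np.zeros_like(state.density_matrix)
        dp[i, j] += h
        fd = (electrostatic_energy(state.density_matrix + dp)
              - electrostatic_energy(state.density_matrix - dp)) / (2 * h)
        assert h1[j, i] == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_missing_onsite_integrals_raise(suite, params):
    p0 = copy.deepcopy(params)
    p0.elements["Y"].dipole_integral = 0.0
    with pytest.raises(ConfigurationError, match="multipole"):
        scc_loop(suite.geometry("XY2"), p0, "dftb2", SCCOptions(multipole=True))
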