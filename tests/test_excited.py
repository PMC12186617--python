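"""Linear-response TD-DFTB: transition charges, coupling, Casida solver."""

import numpy as np
import pytest

import minidftb as md
from minidftb.errors import ConfigurationError, ConsistencyError, NumericError
from minidftb.excited import (
    casida_solve,
    coupling_matrix,
    excitation_spectrum,
    oscillator_strengths,
    transition_charges,
)
from minidftb.oracles import oracle_bank, rpa_full
from minidftb.scc import SCCOptions, build_gamma_matrices, scc_loop


@pytest.fixture(scope="module")
def xy_ground(suite):
    return scc_loop(suite.geometry("XY"), suite.params, "dftb2",
                    SCCOptions(tolerance=1e-11))


# ---------------------------------------------------- transition charges

def test_diagonal_transition_charges_close_to_one(xy_ground):
    gs = xy_ground
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    q_diag = transition_charges(gs.mo_coefficients, gs.overlap, occ, occ,
                                gs.basis)
    for k, i in enumerate(occ):
        col = k * len(occ) + k
        assert q_diag[:, col].sum() == pytest.approx(1.0, abs=1e-10)


def test_offdiagonal_transition_charges_sum_to_zero(xy_ground):
    gs = xy_ground
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    virt = [i for i, o in enumerate(gs.occupations) if o < 0.5]
    q = transition_charges(gs.mo_coefficients, gs.overlap, occ, virt, gs.basis)
    for col in range(q.shape[1]):
        assert abs(q[:, col].sum()) < 1e-10


def test_homonuclear_dimer_bonding_antibonding_pair(suite, params):
    """Explicit 2x2 evaluation: q = +-1/(2 sqrt(1-s^2)), which reduces to
    +-1/2 in the orthogonal-basis limit."""
    gs = scc_loop(suite.geometry("X2"), params, "dftb2")
    q = transition_charges(gs.mo_coefficients, gs.overlap, [0], [1], gs.basis)
    s = gs.overlap[0, 1]
    expected = 1.0 / (2.0 * np.sqrt(1.0 - s * s))
    assert np.abs(q[:, 0]) == pytest.approx([expected, expected], abs=1e-10)
    assert q[0, 0] == pytest.approx(-q[1, 0], abs=1e-10)


def test_non_orthonormal_orbitals_rejected(xy_ground):
    gs = xy_ground
    bad = gs.mo_coefficients.copy()
    bad[:, 0] *= 1.5
    with pytest.raises(ConsistencyError):
        transition_charges(bad, gs.overlap, [0], [1], gs.basis)


# ---------------------------------------------------- coupling matrix

def test_zero_kernels_give_zero_coupling(xy_ground):
    q = np.ones((2, 3)) * 0.1
    k = coupling_matrix(q, np.zeros((2, 2)), np.zeros(2), "singlet")
    assert np.max(np.abs(k)) == 0.0
    k3 = coupling_matrix(q, np.zeros((2, 2)), np.zeros(2), "triplet")
    assert np.max(np.abs(k3)) == 0.0


def test_coupling_matrix_is_symmetric(rng):
    q = rng.normal(size=(3, 6))
    gam = rng.normal(size=(3, 3))
    gam = 0.5 * (gam + gam.T)
    w = rng.normal(size=3)
    for channel in ("singlet", "triplet"):
        k = coupling_matrix(q, gam, w, channel)
        assert np.max(np.abs(k - k.T)) < 1e-12


def test_two_transition_toy_against_four_index_sum():
    q = np.array([[0.3, -0.1], [-0.3, 0.1]])        # atoms x transitions
    gam = np.array([[0.42, 0.2], [0.2, 0.36]])
    k = coupling_matrix(q, gam, np.zeros(2), "singlet")
    for c1 in range(2):
        for c2 in range(2):
            direct = 2.0 * sum(
                q[a, c1] * gam[a, b] * q[b, c2]
                for a in range(2) for b in range(2)
            )
            assert k[c1, c2] == pytest.approx(direct, abs=1e-12)


def test_triplet_uses_onsite_spin_constants():
    q = np.array([[0.4, 0.2], [-0.4, -0.2]])
    w = np.array([-0.07, -0.04])
    k = coupling_matrix(q, np.eye(2), w, "triplet")
    direct = 2.0 * q.T @ np.diag(w) @ q
    assert np.allclose(k, 0.5 * (direct + direct.T), atol=1e-14)


def test_exchange_term_requires_long_range_kernel():
    q = np.ones((2, 1))
    with pytest.raises(ConfigurationError, match="x_c"):
        coupling_matrix(q, np.eye(2), np.zeros(2), "singlet", x_c=1)


# ---------------------------------------------------- Casida solver

def test_zero_coupling_reduces_to_orbital_differences():
    w = np.array([0.3, 0.5, 0.9])
    exc_rpa = casida_solve(w, np.zeros((3, 3)), 3, "rpa")
    exc_tda = casida_solve(w, np.zeros((3, 3)), 3, "tda")
    assert np.allclose(exc_rpa.omegas, w, atol=1e-14)
    assert np.allclose(exc_tda.omegas, w, atol=1e-14)


def test_single_transition_closed_forms():
    w, k = 0.4, 0.05
    exc_rpa = casida_solve(np.array([w]), np.array([[k]]), 1, "rpa")
    exc_tda = casida_solve(np.array([w]), np.array([[k]]), 1, "tda")
    assert exc_rpa.omegas[0] == pytest.approx(
        np.sqrt(w * (w + 2 * k)), abs=1e-12
    )
    assert exc_tda.omegas[0] == pytest.approx(w + k, abs=1e-12)


def test_random_coupling_matches_full_nonhermitian_oracle(rng):
    record = oracle_bank("rpa_6x6_seed0")
    w = record.value["omega"]
    k = record.value["k"]
    exc = casida_solve(w, k, 6, "rpa")
    assert np.max(np.abs(exc.omegas - record.value["eigenvalues"])) \
        < record.tolerance


def test_rpa_normalization_metric(rng):
    w = np.sort(rng.uniform(0.2, 1.0, size=5))
    k = rng.normal(scale=0.03, size=(5, 5))
    k = 0.5 * (k + k.T)
    exc = casida_solve(w, k, 5, "rpa")
    for s in range(5):
        assert exc.xpy[s] @ exc.xmy[s] == pytest.approx(1.0, abs=1e-10)


def test_tda_lowest_root_bounds_rpa(suite, params, rng):
    # random matrices with A-B positive definite
    for _ in range(5):
        n = 4
        w = np.sort(rng.uniform(0.3, 1.0, size=n))
        k = rng.normal(scale=0.04, size=(n, n))
        k = 0.5 * (k + k.T)
        try:
            rpa = casida_solve(w, k, 1, "rpa").omegas[0]
            tda = casida_solve(w, k, 1, "tda").omegas[0]
        except NumericError:
            continue
        assert tda >= rpa - 1e-12
    # and on the molecular fixture
    _, rpa = excitation_spectrum(suite.geometry("XY"), params, "dftb2",
                                 n_states=1, method="rpa")
    _, tda = excitation_spectrum(suite.geometry("XY"), params, "dftb2",
                                 n_states=1, method="tda")
    assert tda.omegas[0] >= rpa.omegas[0] - 1e-12


def test_instability_reported_with_root_index():
    w = np.array([0.1])
    k = np.array([[-0.2]])   # makes omega^2 negative
    with pytest.raises(NumericError, match="root"):
        casida_solve(w, k, 1, "rpa")


def test_oversized_state_request_rejected():
    with pytest.raises(ConfigurationError, match="transition space"):
        casida_solve(np.array([0.4]), np.zeros((1, 1)), 3, "rpa")


# ---------------------------------------------------- full spectra

def test_molecular_rpa_matches_dense_oracle(suite, params):
    geom = suite.geometry("XY2")
    gs, exc = excitation_spectrum(geom, params, "dftb2", n_states=4,
                                  method="rpa")
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    virt = [i for i, o in enumerate(gs.occupations) if o < 0.5]
    pairs = [(i, a) for i in occ for a in virt]
    q = transition_charges(gs.mo_coefficients, gs.overlap, occ, virt, gs.basis)
    gamma_mat, _ = build_gamma_matrices(geom, params, SCCOptions().kernel())
    w_const = np.array([params.element(s).spin_constant for s in geom.symbols])
    k = coupling_matrix(q, gamma_mat, w_const, "singlet")
    w_ia = np.array([gs.mo_energies[a] - gs.mo_energies[i] for i, a in pairs])
    ref = rpa_full(w_ia, k, 4)
    assert np.max(np.abs(exc.omegas - ref)) < 1e-10


def test_triplet_channel_with_zero_spin_constants_is_bare(suite, params):
    import copy

    p0 = copy.deepcopy(params)
    for el in p0.elements.values():
        el.spin_constant = 0.0
    geom = suite.geometry("XY")
    gs, exc = excitation_spectrum(geom, p0, "dftb2", n_states=3,
                                  method="rpa", channel="triplet")
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    virt = [i for i, o in enumerate(gs.occupations) if o < 0.5]
    w_ia = np.sort([gs.mo_energies[a] - gs.mo_energies[i]
                    for i in occ for a in virt])
    assert np.allclose(exc.omegas, w_ia[:3], atol=1e-12)


def test_triplet_oscillator_strengths_vanish(suite, params):
    _, exc = excitation_spectrum(suite.geometry("XY"), params, "dftb2",
                                 n_states=3, channel="triplet")
    assert np.all(exc.oscillator_strengths == 0.0)


def test_centrosymmetric_gerade_transition_is_dark(suite, params):
    """In the X4 chain, transitions between same-parity orbitals carry no
    transition dipole."""
    geom = suite.geometry("X4")
    gs, exc = excitation_spectrum(geom, params, "dftb2", n_states=4)
    # MOs of the centrosymmetric chain alternate parity (g, u, g, u);
    # occupied = {g, u}; the u->u and g->g transitions must be dark
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    virt = [i for i, o in enumerate(gs.occupations) if o < 0.5]
    q = transition_charges(gs.mo_coefficients, gs.overlap, occ, virt, gs.basis)
    pairs = [(i, a) for i in occ for a in virt]
    dark = 0
    for col, (i, a) in enumerate(pairs):
        mu = q[:, col] @ geom.positions
        if (a - i) % 2 == 0:   # same parity
            assert np.linalg.norm(mu) < 1e-10
            dark += 1
    assert dark >= 2


def test_oscillator_strengths_match_direct_summation(suite, params):
    geom = suite.geometry("XY2")
    gs, exc = excitation_spectrum(geom, params, "dftb2", n_states=4)
    occ = [i for i, o in enumerate(gs.occupations) if o > 1.5]
    virt = [i for i, o in enumerate(gs.occupations) if o < 0.5]
    q = transition_charges(gs.mo_coefficients, gs.overlap, occ, virt, gs.basis)
    for s in range(4):
        mu = np.zeros(3)
        for col in range(q.shape[1]):
            for a in range(geom.n_atoms):
                mu += geom.positions[a] * q[a, col] * exc.xpy[s][col]
        f_ref = (2.0 / 3.0) * exc.omegas[s] * mu @ mu
        assert exc.oscillator_strengths[s] == pytest.approx(f_ref, abs=1e-12)
        assert exc.oscillator_strengths[s] >= 0.0


def test_synthetic_long_range_kernel_exchange_path(suite, params):
    """x_c = 1 with a synthetic gamma_CAM table lowers the coupling."""
    geom = suite.geometry("XY")
    gamma_cam = np.full((2, 2), 0.05) + np.eye(2) * 0.1
    gs, exc0 = excitation_spectrum(geom, params, "dftb2", n_states=2)
    gs, exc1 = excitation_spectrum(geom, params, "dftb2", n_states=2,
                                   x_c=1, gamma_cam=gamma_cam)
    assert exc1.omegas[0] != pytest.approx(exc0.omegas[0], abs=1e-9)


def test_state_request_validated_before_compute(suite, params):
    with pytest.raises(ConfigurationError, match="transition space"):
        excitation_spectrum(suite.geometry("X2"), params, "dftb2",
                            n_states=10)
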