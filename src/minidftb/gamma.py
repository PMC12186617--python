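"""Second-order charge-fluctuation kernels.

The SCC Coulomb kernel gamma_AB(R) is the analytic Coulomb integral of two
spherical exponential charge densities rho_A(r) = tau_A^3/(8 pi) exp(-tau_A r)
whose decay constants are tied to the chemical hardness, tau = (16/5) U, so
that the on-site limit gamma_AA(0) = U_A.

Internally gamma is represented as a sum of terms

    exp(-t R - g R^2) * sum_k c_k R^k      (k may be negative)

which is closed under d/dR; radial derivatives up to fourth order (needed by
the multipolar Taylor expansion) are therefore analytic, and the hydrogen-pair
damped variant gamma^h -- which multiplies the short-range part by
exp(-((U_A+U_B)/2)^zeta R^2) -- fits the same representation via the Gaussian
exponent g.

The third-order kernel Gamma_AB = d gamma_AB / d q_A is evaluated through the
Hubbard-derivative chain rule, Gamma = (d gamma / d U_A) * U_A^d, with the
U-derivative taken by high-precision central differences (mpmath), which also
covers the damped variant where the exponent itself depends on U_A. The same
high-precision route backs evaluation at tiny separations and for nearly equal
decay constants, where the closed-form branches cancel catastrophically in
double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import mpmath as mp

from .errors import DomainError

TAU_FACTOR = 16.0 / 5.0

# switch to high-precision evaluation below these thresholds
_R_SMALL = 1e-4
_TAU_DEGENERATE = 1e-4  # relative |tau_a - tau_b| threshold
_MP_DPS = 35


def hubbard_to_tau(u: float):
    return TAU_FACTOR * u


# ------------------------------------------------------------- term algebra
# a term is (t, g, {k: c}) representing exp(-t R - g R^2) * sum_k c_k R^k

def _gamma_terms(tau_a, tau_b, damp, one):
    """Terms of gamma = 1/R - S(R); ``one`` fixes the number type (1.0 or mpf)."""
    ta, tb = tau_a * one, tau_b * one
    terms = [(0 * one, 0 * one, {-1: one})]
    if ta == tb:
        t = ta
        terms.append((t, damp * one, {
            -1: -one,
            0: -11 * t / 16,
            1: -3 * t * t / 16,
            2: -t * t * t / 48,
        }))
    else:
        fa = ta * tb ** 4 / (2 * (ta ** 2 - tb ** 2) ** 2)
        ga = -(tb ** 6 - 3 * ta ** 2 * tb ** 4) / (ta ** 2 - tb ** 2) ** 3
        fb = tb * ta ** 4 / (2 * (tb ** 2 - ta ** 2) ** 2)
        gb = -(ta ** 6 - 3 * tb ** 2 * ta ** 4) / (tb ** 2 - ta ** 2) ** 3
        terms.append((ta, damp * one, {0: -fa, -1: -ga}))
        terms.append((tb, damp * one, {0: -fb, -1: -gb}))
    return terms


def _deriv_terms(terms):
    out = []
    for t, g, coeffs in terms:
        new: dict = {}
        for k, c in coeffs.items():
            new[k] = new.get(k, 0) - t * c
            new[k + 1] = new.get(k + 1, 0) - 2 * g * c
            if k != 0:
                new[k - 1] = new.get(k - 1, 0) + k * c
        out.append((t, g, new))
    return out


def _eval_terms(terms, r, use_mp: bool):
    exp = mp.exp if use_mp else math.exp
    total = 0
    for t, g, coeffs in terms:
        e = exp(-t * r - g * r * r)
        total += e * sum(c * r ** k for k, c in coeffs.items())
    return total


def _series_coeffs(terms, kmax: int):
    """Coefficients of R^-1 .. R^kmax of the summed terms around R = 0."""
    acc = {k: 0 for k in range(-1, kmax + 1)}
    for t, g, coeffs in terms:
        # exp(-tR - gR^2) series up to R^(kmax+1)
        es = [0] * (kmax + 2)
        es[0] = 1
        # multiply by exp(-tR)
        ser = [((-t) ** j) / math.factorial(j) if not isinstance(t, mp.mpf)
               else ((-t) ** j) / mp.factorial(j) for j in range(kmax + 2)]
        # multiply by exp(-gR^2)
        full = [0] * (kmax + 2)
        m = 0
        while 2 * m <= kmax + 1:
            gm = ((-g) ** m) / (mp.factorial(m) if isinstance(g, mp.mpf)
                                else math.factorial(m))
            for j in range(kmax + 2 - 2 * m):
                full[j + 2 * m] += gm * ser[j]
            m += 1
        for k, c in coeffs.items():
            for j in range(kmax + 2):
                p = k + j
                if -1 <= p <= kmax:
                    acc[p] += c * full[j]
    return acc


# ------------------------------------------------------------- public API

def _validate(u_a: float, u_b: float, r: float) -> None:
    if u_a <= 0 or u_b <= 0:
        raise DomainError("Hubbard U must be positive")
    if r < 0:
        raise DomainError("distance must be non-negative")


def gamma_onsite(u_a: float, u_b: float) -> float:
    """gamma_AB at R = 0 (the damped variant coincides there)."""
    ta, tb = hubbard_to_tau(u_a), hubbard_to_tau(u_b)
    return ta * tb * (ta ** 2 + 3 * ta * tb + tb ** 2) / (2 * (ta + tb) ** 3)


@lru_cache(maxsize=512)
def _small_r_coeffs_cached(u_a: float, u_b: float) -> tuple:
    return gamma_small_r_coeffs(u_a, u_b, 0.0)


def _needs_mp(tau_a: float, tau_b: float, r: float) -> bool:
    if r < _R_SMALL:
        return True
    rel = abs(tau_a - tau_b) / (tau_a + tau_b)
    return 0.0 < rel < _TAU_DEGENERATE


def gamma_value(u_a: float, u_b: float, r: float, damp: float = 0.0) -> float:
    """gamma_AB(R) in hartree; ``damp`` is the Gaussian exponent of gamma^h."""
    _validate(u_a, u_b, r)
    if r == 0.0:
        return gamma_onsite(u_a, u_b)
    if r < 1e-3:
        # even Taylor series; the direct forms cancel 1/R-scale terms there
        c0, c2, c4 = _small_r_coeffs_cached(u_a, u_b)
        g_undamped = c0 + c2 * r * r + c4 * r ** 4
        if damp == 0.0:
            return g_undamped
        short = 1.0 / r - g_undamped
        return g_undamped + short * (-math.expm1(-damp * r * r))
    ta, tb = hubbard_to_tau(u_a), hubbard_to_tau(u_b)
    if _needs_mp(ta, tb, r):
        with mp.workdps(_MP_DPS):
            terms = _gamma_terms(mp.mpf(ta), mp.mpf(tb), mp.mpf(damp), mp.mpf(1))
            return float(_eval_terms(terms, mp.mpf(r), True))
    terms = _gamma_terms(ta, tb, damp, 1.0)
    return float(_eval_terms(terms, r, False))


def gamma_radial_derivatives(
    u_a: float, u_b: float, r: float, damp: float = 0.0, order: int = 4
) -> list[float]:
    """[gamma, gamma', ..., gamma^(order)] with respect to R, analytic."""
    _validate(u_a, u_b, r)
    if r <= 0.0:
        raise DomainError("radial derivatives need R > 0; use the on-site limit")
    ta, tb = hubbard_to_tau(u_a), hubbard_to_tau(u_b)
    use_mp = _needs_mp(ta, tb, r)
    if use_mp:
        with mp.workdps(_MP_DPS):
            terms = _gamma_terms(mp.mpf(ta), mp.mpf(tb), mp.mpf(damp), mp.mpf(1))
            out = []
            for _ in range(order + 1):
                out.append(float(_eval_terms(terms, mp.mpf(r), True)))
                terms = _deriv_terms(terms)
            return out
    terms = _gamma_terms(ta, tb, damp, 1.0)
    out = []
    for _ in range(order + 1):
        out.append(float(_eval_terms(terms, r, False)))
        terms = _deriv_terms(terms)
    return out


def gamma_small_r_coeffs(u_a: float, u_b: float, damp: float = 0.0) -> tuple:
    """Even Taylor coefficients (c0, c2, c4) of gamma(R) around R = 0.

    The odd coefficients and the 1/R pole cancel identically between the bare
    Coulomb term and the short-range part; they are verified to vanish and
    discarded. Used for the on-site (A = B) multipole kernels.
    """
    _validate(u_a, u_b, 1.0)
    ta, tb = hubbard_to_tau(u_a), hubbard_to_tau(u_b)
    with mp.workdps(_MP_DPS):
        terms = _gamma_terms(mp.mpf(ta), mp.mpf(tb), mp.mpf(damp), mp.mpf(1))
        acc = _series_coeffs(terms, 4)
        for k in (-1, 1, 3):
            if abs(acc[k]) > 1e-10:
                raise ArithmeticError(
                    f"odd/singular series coefficient R^{k} did not cancel"
                )
        return float(acc[0]), float(acc[2]), float(acc[4])


@dataclass
class GammaKernel:
    """Kernel configuration: plain DFTB2 gamma or the hydrogen-damped gamma^h."""

    variant: str = "plain"       # 'plain' | 'gamma_h'
    zeta: float = 4.0            # damping exponent of gamma^h

    def damping(self, u_a: float, u_b: float, hydrogen_pair: bool) -> float:
        if self.variant == "gamma_h" and hydrogen_pair:
            return (0.5 * (u_a + u_b)) ** self.zeta
        return 0.0


def _gamma_of_u(kernel: GammaKernel, u_a, u_b, r, hydrogen_pair: bool, use_mp: bool):
    """gamma as a function of the Hubbard parameters (damping included)."""
    damp = kernel.damping(float(u_a), float(u_b), hydrogen_pair)
    if use_mp:
        ta, tb = TAU_FACTOR * u_a, TAU_FACTOR * u_b
        if r == 0:
            return ta * tb * (ta ** 2 + 3 * ta * tb + tb ** 2) / (2 * (ta + tb) ** 3)
        terms = _gamma_terms(ta, tb, mp.mpf(damp), mp.mpf(1))
        return _eval_terms(terms, r, True)
    return gamma_value(float(u_a), float(u_b), float(r), damp)


def gamma_hubbard_derivative(
    kernel: GammaKernel, u_a: float, u_b: float, r: float,
    hydrogen_pair: bool = False,
) -> float:
    """d gamma_AB / d U_A, including any U-dependence of the gamma^h damping."""
    _validate(u_a, u_b, r)
    # the centered step perturbs tau into the nearly-degenerate regime where
    # the closed-form coefficients cancel catastrophically; 50 digits leave
    # ample headroom for the ~1e17 coefficient growth at h ~ 1e-6 U
    with mp.workdps(50):
        ua = mp.mpf(u_a)
        h = ua * mp.mpf("1e-6")
        rr = mp.mpf(r)
        up = _gamma_of_u(kernel, ua + h, mp.mpf(u_b), rr, hydrogen_pair, True)
        dn = _gamma_of_u(kernel, ua - h, mp.mpf(u_b), rr, hydrogen_pair, True)
        return float((up - dn) / (2 * h))


def gamma_pair(
    kernel: GammaKernel,
    u_a: float,
    u_b: float,
    r: float,
    hydrogen_pair: bool = False,
    hubbard_derivative_a: float = 0.0,
) -> tuple[float, float]:
    """(gamma_AB, Gamma_AB) for one atom pair at separation R (bohr).

    Gamma_AB = (d gamma / d U_A) * U_A^d; it vanishes when the Hubbard
    derivative is zero, which collapses DFTB3 onto DFTB2.
    """
    _validate(u_a, u_b, r)
    damp = kernel.damping(u_a, u_b, hydrogen_pair)
    g = gamma_value(u_a, u_b, r, damp)
    if hubbard_derivative_a == 0.0:
        return g, 0.0
    dg_du = gamma_hubbard_derivative(kernel, u_a, u_b, r, hydrogen_pair)
    return g, dg_du * hubbard_derivative_a
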