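"""Closed-form two-center overlap integrals for Slater 1s / 2p orbitals.

The integrals are evaluated in prolate-spheroidal coordinates, where every
s/p overlap reduces to products of the classical auxiliary functions

    A_n(p) = int_1^inf  x^n exp(-p x) dx
    B_n(q) = int_{-1}^1 x^n exp(-q x) dx

The normalized orbitals are

    1s : (zeta^3/pi)^(1/2)           exp(-zeta r)
    2p : (zeta^5/pi)^(1/2) r Y(theta,phi) exp(-zeta r)

with real angular parts (sigma along the internuclear axis, pi perpendicular).
Sign convention: the axis points from the first atom to the second, and a
sigma p orbital is taken with its positive lobe along +z on *both* centers.
"""

from __future__ import annotations

import math

__all__ = ["aux_a", "aux_b", "overlap_ss", "overlap_sp", "overlap_pp_sigma",
           "overlap_pp_pi", "sto_overlap"]


def aux_a(n: int, p: float) -> float:
    """A_n(p) for p > 0, by the stable upward recursion."""
    if p <= 0.0:
        raise ValueError("A_n requires p > 0")
    e = math.exp(-p)
    val = e / p  # A_0
    for k in range(1, n + 1):
        val = (e + k * val) / p
    return val


def aux_b(n: int, q: float) -> float:
    """B_n(q); series for small |q| (the upward recursion is unstable there)."""
    if abs(q) < 0.5:
        # B_n(q) = sum_k (-q)^k/k! * [2/(n+k+1) if n+k even else 0]
        total, term = 0.0, 1.0
        for k in range(0, 40):
            if (n + k) % 2 == 0:
                total += term * 2.0 / (n + k + 1)
            term *= -q / (k + 1)
            if abs(term) < 1e-18 and k > n + 4:
                break
        return total
    val = 2.0 * math.sinh(q) / q  # B_0
    ep, em = math.exp(q), math.exp(-q)
    for k in range(1, n + 1):
        val = (((-1) ** k) * ep - em) / q + k * val / q
    return val


def _pq(zeta_a: float, zeta_b: float, r: float) -> tuple[float, float]:
    return 0.5 * r * (zeta_a + zeta_b), 0.5 * r * (zeta_a - zeta_b)


def overlap_ss(zeta_a: float, zeta_b: float, r: float) -> float:
    """<1s(A)|1s(B)> at separation r (bohr)."""
    if r == 0.0:
        # overlap of two 1s Slater functions on the same center
        return 8.0 * (zeta_a * zeta_b) ** 1.5 / (zeta_a + zeta_b) ** 3
    p, q = _pq(zeta_a, zeta_b, r)
    pref = (zeta_a * zeta_b) ** 1.5 * 2.0 * (r / 2.0) ** 3
    return pref * (aux_a(2, p) * aux_b(0, q) - aux_a(0, p) * aux_b(2, q))


def overlap_sp(zeta_s: float, zeta_p: float, r: float) -> float:
    """<1s(A)|2p_sigma(B)>; p orbital on the second center, lobe along +z."""
    if r == 0.0:
        return 0.0  # orthogonal angular parts on one center
    p, q = _pq(zeta_s, zeta_p, r)
    pref = (zeta_s ** 3 * zeta_p ** 5) ** 0.5 * 2.0 * (r / 2.0) ** 4
    return pref * (
        aux_a(3, p) * aux_b(1, q) - aux_a(2, p) * aux_b(0, q)
        - aux_a(1, p) * aux_b(3, q) + aux_a(0, p) * aux_b(2, q)
    )


def overlap_pp_sigma(zeta_a: float, zeta_b: float, r: float) -> float:
    """<2p_sigma(A)|2p_sigma(B)>, both lobes along +z."""
    if r == 0.0:
        return 32.0 * (zeta_a * zeta_b) ** 2.5 / (zeta_a + zeta_b) ** 5
    p, q = _pq(zeta_a, zeta_b, r)
    pref = (zeta_a * zeta_b) ** 2.5 * 2.0 * (r / 2.0) ** 5
    return pref * (
        aux_a(4, p) * aux_b(2, q) - aux_a(2, p) * aux_b(0, q)
        - aux_a(2, p) * aux_b(4, q) + aux_a(0, p) * aux_b(2, q)
    )


def overlap_pp_pi(zeta_a: float, zeta_b: float, r: float) -> float:
    """<2p_pi(A)|2p_pi(B)>."""
    if r == 0.0:
        return 32.0 * (zeta_a * zeta_b) ** 2.5 / (zeta_a + zeta_b) ** 5
    p, q = _pq(zeta_a, zeta_b, r)
    pref = (zeta_a * zeta_b) ** 2.5 * (r / 2.0) ** 5
    return pref * (
        aux_a(4, p) * aux_b(0, q) - aux_a(4, p) * aux_b(2, q)
        - aux_a(2, p) * aux_b(0, q) + aux_a(2, p) * aux_b(4, q)
        + aux_a(0, p) * aux_b(2, q) - aux_a(0, p) * aux_b(4, q)
    )


_CHANNELS = {
    "sss": lambda za, zb, r: overlap_ss(za, zb, r),
    "sps": lambda za, zb, r: overlap_sp(za, zb, r),
    "pps": lambda za, zb, r: overlap_pp_sigma(za, zb, r),
    "ppp": lambda za, zb, r: overlap_pp_pi(za, zb, r),
}


def sto_overlap(channel: str, zeta_a: float, zeta_b: float, r: float) -> float:
    """Overlap for a named bond channel ('sss', 'sps', 'pps', 'ppp')."""
    try:
        fn = _CHANNELS[channel]
    except KeyError:
        raise ValueError(f"unsupported channel {channel!r} for the s/p basis") from None
    return fn(zeta_a, zeta_b, r)
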