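"""Slater-Koster transformation: tabulated bond integrals -> molecular frame.

Tabulated integrals are stored per bond channel (ssσ, spσ, ppσ, ppπ, ...)
along the internuclear axis; the dense (2l1+1)x(2l2+1) matrix blocks for an
arbitrary orientation follow from direction-cosine combinations. Real p
orbitals are ordered (x, y, z).

Conventions: the direction vector points from the first (bra) atom to the
second (ket) atom; spσ is tabulated with the s orbital on the first atom.
Swapping the atoms transposes the block and multiplies by (-1)^(l1+l2).
"""

from __future__ import annotations

import numpy as np

from .errors import CapabilityError
from .skf import SlaterKosterTable


def sk_rotate(
    table_12: SlaterKosterTable,
    table_21: SlaterKosterTable,
    l1: int,
    l2: int,
    direction: np.ndarray,
    r: float,
    matrix: str = "H",
) -> np.ndarray:
    """Dense H or S sub-block for a shell pair at separation ``r``.

    ``table_12`` holds the channels for the ordered pair (atom1, atom2),
    ``table_21`` for the reversed order (needed for the p-s block of a
    heteronuclear pair; for homonuclear pairs pass the same table twice).
    ``direction`` is the unit vector from atom 1 to atom 2.
    """
    n = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"direction vector not normalized (|n| = {norm:.6g})")
    n = n / norm

    if (l1, l2) == (0, 0):
        return np.array([[table_12.interpolate("sss", matrix, r)]])
    if (l1, l2) == (0, 1):
        sps = table_12.interpolate("sps", matrix, r)
        return (sps * n).reshape(1, 3)
    if (l1, l2) == (1, 0):
        # <p(1)|s(2)> = transpose of <s(2)|p(1)> taken along the reversed axis
        sps = table_21.interpolate("sps", matrix, r)
        return (-sps * n).reshape(3, 1)
    if (l1, l2) == (1, 1):
        pps = table_12.interpolate("pps", matrix, r)
        ppp = table_12.interpolate("ppp", matrix, r)
        nn = np.outer(n, n)
        return pps * nn + ppp * (np.eye(3) - nn)
    raise CapabilityError(
        f"shell pair (l1={l1}, l2={l2}) not supported: s and p shells only"
    )
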