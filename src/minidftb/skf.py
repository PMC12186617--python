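"""Classic Slater-Koster (.skf) parameter tables: parsing, writing, lookup.

Supported dialect (classic, non-extended):

* line 1: ``grid_spacing n_points``
* homonuclear only, line 2: ``Ed Ep Es SPE Ud Up Us fd fp fs``
* next line: ``mass c2 c3 c4 c5 c6 c7 c8 c9 rcut 10x0`` (polynomial repulsive)
* ``n_points`` rows of 20 columns: ``Hdd0 Hdd1 Hdd2 Hpd0 Hpd1 Hpp0 Hpp1
  Hsd0 Hsp0 Hss0`` then the same ten channels for S
* optional trailing ``Spline`` block: ``n cutoff``, exponential head
  ``a1 a2 a3``, ``n-1`` cubic rows ``start end c0 c1 c2 c3`` and a final
  fifth-order row with two extra coefficients.

Extended-format files (starting with ``@``) are rejected. All quantities are
atomic units (hartree / bohr).

Radial table lookup uses piecewise polynomial interpolation through
``NPOINT_INTERP`` neighboring grid points, with a smooth fifth-order tail to
zero over ``TAIL_LENGTH`` bohr past the last grid point. Distances beyond the
tail raise :class:`~minidftb.errors.TableRangeError` (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError, ParseError, TableRangeError

#: channel order of the 20 H/S columns in a classic skf table
CHANNELS = ("dds", "ddp", "ddd", "pds", "pdp", "pps", "ppp", "sds", "sps", "sss")
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

NPOINT_INTERP = 8      # points used by the local interpolating polynomial
TAIL_LENGTH = 0.25     # bohr; fifth-order decay to zero past the grid end


@dataclass
class RepulsiveSpline:
    """Spline repulsive: exponential head, cubic knots, fifth-order last segment."""

    cutoff: float
    head: tuple[float, float, float]            # exp(-a1*r + a2) + a3 below first knot
    segments: list[tuple[float, float, tuple[float, ...]]]  # (start, end, coeffs)

    def __call__(self, r: float) -> float:
        if r >= self.cutoff:
            return 0.0
        if r < self.segments[0][0]:
            a1, a2, a3 = self.head
            return float(np.exp(-a1 * r + a2) + a3)
        for start, end, coeffs in self.segments:
            if start <= r < end or (end == self.segments[-1][1] and r <= end):
                dr = r - start
                return float(sum(c * dr ** k for k, c in enumerate(coeffs)))
        return 0.0


@dataclass
class RepulsivePolynomial:
    """Polynomial repulsive sum_k=2..9 c_k (rcut - r)^k, zero beyond rcut."""

    cutoff: float
    coeffs: tuple[float, ...]  # c2..c9

    def __call__(self, r: float) -> float:
        if r >= self.cutoff:
            return 0.0
        x = self.cutoff - r
        return float(sum(c * x ** (k + 2) for k, c in enumerate(self.coeffs)))


@dataclass
class OnsiteBlock:
    """Homonuclear on-site data: energies, Hubbard U and occupations per shell."""

    energies: dict[str, float]     # keys 'd','p','s'
    spe: float
    hubbard: dict[str, float]
    occupations: dict[str, float]


@dataclass
class SlaterKosterTable:
    grid_spacing: float
    n_points: int
    hs: np.ndarray                       # (n_points, 20): H channels then S channels
    mass: float = 0.0
    onsite: OnsiteBlock | None = None    # homonuclear only
    repulsive: RepulsiveSpline | RepulsivePolynomial | None = None
    elements: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ParseError("grid spacing must be positive")
        if self.n_points < 2:
            raise ParseError("table needs at least two grid points")
        self.hs = np.asarray(self.hs, dtype=float)
        if self.hs.shape != (self.n_points, 20):
            raise ParseError(
                f"H/S table shape {self.hs.shape}, expected ({self.n_points}, 20)"
            )

    # ---- grid ----
    @property
    def r_grid(self) -> np.ndarray:
        return self.grid_spacing * np.arange(1, self.n_points + 1)

    @property
    def r_max(self) -> float:
        """Largest usable distance (grid end plus the decay tail)."""
        return self.grid_spacing * self.n_points + TAIL_LENGTH

    # ---- lookup ----
    def _column(self, channel: str, matrix: str) -> np.ndarray:
        off = 0 if matrix == "H" else 10
        return self.hs[:, off + CHANNEL_INDEX[channel]]

    def interpolate(self, channel: str, matrix: str, r: float) -> float:
        """Interpolated H or S bond integral at distance r (bohr)."""
        col = self._column(channel, matrix)
        return _interp_table(self.r_grid, col, r, self.grid_spacing)

    def evaluate_repulsive(self, r: float) -> float:
        if self.repulsive is None:
            return 0.0
        return self.repulsive(r)


def _lagrange_eval(xs: np.ndarray, ys: np.ndarray, x: float) -> float:
    """Barycentric Lagrange evaluation through the given nodes."""
    diffs = x - xs
    hit = np.where(np.abs(diffs) < 1e-14)[0]
    if hit.size:
        return float(ys[hit[0]])
    w = np.ones(len(xs))
    for i in range(len(xs)):
        for j in range(len(xs)):
            if i != j:
                w[i] /= xs[i] - xs[j]
    num = np.sum(w * ys / diffs)
    den = np.sum(w / diffs)
    return float(num / den)


def _interp_table(grid: np.ndarray, values: np.ndarray, r: float, dr: float) -> float:
    r_last = grid[-1]
    n = len(grid)
    if r < grid[0]:
        # below the first tabulated point: extrapolate the first-interval
        # polynomial (tables are expected to start well inside bonding range)
        idx0 = 0
    elif r <= r_last:
        k = int(np.searchsorted(grid, r))
        idx0 = min(max(k - NPOINT_INTERP // 2, 0), n - NPOINT_INTERP)
    else:
        # fifth-order tail to zero over TAIL_LENGTH
        r_end = r_last + TAIL_LENGTH
        if r > r_end + 1e-12:
            raise TableRangeError(
                f"distance {r:.4f} bohr beyond table range {r_end:.4f} bohr"
            )
        idx0 = n - NPOINT_INTERP
        xs = grid[idx0:idx0 + NPOINT_INTERP]
        ys = values[idx0:idx0 + NPOINT_INTERP]
        f0 = _lagrange_eval(xs, ys, r_last)
        h = dr * 1e-3
        f1 = (_lagrange_eval(xs, ys, r_last) - _lagrange_eval(xs, ys, r_last - h)) / h
        f2 = (_lagrange_eval(xs, ys, r_last) - 2 * _lagrange_eval(xs, ys, r_last - h)
              + _lagrange_eval(xs, ys, r_last - 2 * h)) / h ** 2
        t = (r - r_last) / TAIL_LENGTH
        L = TAIL_LENGTH
        # quintic with value/f'/f'' at t=0 and 0/0/0 at t=1
        c0, c1, c2 = f0, f1 * L, 0.5 * f2 * L * L
        c3 = -10 * c0 - 6 * c1 - 3 * c2
        c4 = 15 * c0 + 8 * c1 + 3 * c2
        c5 = -6 * c0 - 3 * c1 - c2
        return float(c0 + c1 * t + c2 * t ** 2 + c3 * t ** 3 + c4 * t ** 4 + c5 * t ** 5)
    xs = grid[idx0:idx0 + NPOINT_INTERP]
    ys = values[idx0:idx0 + NPOINT_INTERP]
    return _lagrange_eval(xs, ys, r)


# ---------------------------------------------------------------- parsing

def _floats(line: str, path, lineno: int) -> list[float]:
    out = []
    for tok in line.replace(",", " ").split():
        if tok == "*":
            continue
        try:
            out.append(float(tok))
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric token {tok!r}") from None
    return out


def read_skf(path, element_pair: tuple[str, str]) -> SlaterKosterTable:
    """Parse a classic .skf file for the given ordered element pair."""
    e1, e2 = element_pair
    homonuclear = e1 == e2
    with open(path) as fh:
        raw = fh.read().splitlines()
    if raw and raw[0].lstrip().startswith("@"):
        raise ParseError(
            f"{path}: extended-format skf files ('@' header) are not supported; "
            "classic format only"
        )
    lines = [ln for ln in raw if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")

    head = _floats(lines[0], path, 1)
    if len(head) < 2:
        raise ParseError(f"{path}: line 1 must hold grid spacing and point count")
    grid_spacing = head[0]
    n_points = int(round(head[1]))
    if grid_spacing <= 0 or n_points < 2:
        raise ParseError(f"{path}: line 1: invalid grid ({grid_spacing}, {n_points})")

    spline_at = next((i for i, ln in enumerate(lines)
                      if ln.strip().lower() == "spline"), None)
    body = lines[1:spline_at] if spline_at is not None else lines[1:]

    n_pre = 2 if homonuclear else 1  # onsite line (homo only) + mass/poly line
    if len(body) != n_pre + n_points:
        kind = "homonuclear" if homonuclear else "heteronuclear"
        raise LayoutError(
            f"{path}: {kind} layout for pair {e1}-{e2} expects {n_pre + n_points} "
            f"data lines before any Spline block, found {len(body)}; "
            "check the declared element pair"
        )

    cursor = 0
    onsite = None
    if homonuclear:
        vals = _floats(body[0], path, 2)
        if len(vals) < 10:
            raise ParseError(f"{path}: homonuclear on-site line needs 10 values")
        ed, ep, es, spe, ud, up, us, fd, fp, fs = vals[:10]
        onsite = OnsiteBlock(
            energies={"d": ed, "p": ep, "s": es},
            spe=spe,
            hubbard={"d": ud, "p": up, "s": us},
            occupations={"d": fd, "p": fp, "s": fs},
        )
        cursor = 1
    massline = _floats(body[cursor], path, cursor + 2)
    if len(massline) < 10:
        raise ParseError(f"{path}: mass/polynomial line needs at least 10 values")
    mass = massline[0]
    poly_coeffs = tuple(massline[1:9])
    poly_rcut = massline[9]
    cursor += 1

    rows = []
    for k in range(n_points):
        vals = _floats(body[cursor + k], path, cursor + k + 2)
        if len(vals) != 20:
            raise ParseError(
                f"{path}: table row {k + 1} has {len(vals)} columns, expected 20"
            )
        rows.append(vals)
    hs = np.array(rows)

    repulsive: RepulsiveSpline | RepulsivePolynomial | None
    if spline_at is not None:
        repulsive = _parse_spline(lines[spline_at + 1:], path, spline_at + 1)
    elif any(c != 0.0 for c in poly_coeffs):
        repulsive = RepulsivePolynomial(cutoff=poly_rcut, coeffs=poly_coeffs)
    else:
        repulsive = None

    return SlaterKosterTable(
        grid_spacing=grid_spacing, n_points=n_points, hs=hs, mass=mass,
        onsite=onsite, repulsive=repulsive, elements=(e1, e2),
    )


def _parse_spline(lines: list[str], path, base: int) -> RepulsiveSpline:
    if len(lines) < 3:
        raise ParseError(f"{path}: Spline block truncated (missing terminator row)")
    n_cut = _floats(lines[0], path, base + 1)
    if len(n_cut) < 2:
        raise ParseError(f"{path}: Spline block needs 'nInt cutoff' line")
    n_int, cutoff = int(round(n_cut[0])), n_cut[1]
    headvals = _floats(lines[1], path, base + 2)
    if len(headvals) < 3:
        raise ParseError(f"{path}: Spline exponential head needs a1 a2 a3")
    if len(lines) < 2 + n_int:
        raise ParseError(
            f"{path}: Spline block declares {n_int} intervals but ends early "
            "(missing fifth-order terminator segment)"
        )
    segments = []
    for k in range(n_int):
        vals = _floats(lines[2 + k], path, base + 3 + k)
        want = 8 if k == n_int - 1 else 6
        if len(vals) != want:
            raise ParseError(
                f"{path}: Spline segment {k + 1} has {len(vals)} values, "
                f"expected {want}"
            )
        segments.append((vals[0], vals[1], tuple(vals[2:])))
    return RepulsiveSpline(cutoff=cutoff, head=tuple(headvals[:3]), segments=segments)


# ---------------------------------------------------------------- writing

def _fmt(x: float) -> str:
    return f"{x:.16E}"


def write_skf(path, table: SlaterKosterTable) -> None:
    """Write a table in the classic dialect (canonical formatting)."""
    out = [f"{_fmt(table.grid_spacing)} {table.n_points}"]
    if table.onsite is not None:
        ob = table.onsite
        out.append(" ".join(_fmt(v) for v in (
            ob.energies["d"], ob.energies["p"], ob.energies["s"], ob.spe,
            ob.hubbard["d"], ob.hubbard["p"], ob.hubbard["s"],
            ob.occupations["d"], ob.occupations["p"], ob.occupations["s"],
        )))
    if isinstance(table.repulsive, RepulsivePolynomial):
        massline = [table.mass, *table.repulsive.coeffs, table.repulsive.cutoff]
    else:
        massline = [table.mass] + [0.0] * 9
    out.append(" ".join(_fmt(v) for v in massline + [0.0] * 10))
    for row in table.hs:
        out.append(" ".join(_fmt(v) for v in row))
    if isinstance(table.repulsive, RepulsiveSpline):
        rep = table.repulsive
        out.append("Spline")
        out.append(f"{len(rep.segments)} {_fmt(rep.cutoff)}")
        out.append(" ".join(_fmt(v) for v in rep.head))
        for start, end, coeffs in rep.segments:
            out.append(" ".join(_fmt(v) for v in (start, end, *coeffs)))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def evaluate_repulsive(table: SlaterKosterTable, r: float) -> float:
    """Pair repulsive energy at distance r (hartree); exactly 0 at/after cutoff."""
    if r <= 0:
        raise ValueError("repulsive requires r > 0")
    return table.evaluate_repulsive(r)
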