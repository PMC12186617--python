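"""Electronic parameter sets: element data, pair tables, synthetic generation.

A :class:`ParameterSet` couples per-element electronic parameters (shell
structure, Hubbard U and its charge derivative, spin constant, on-site
multipole integrals, Born radius) with per-pair :class:`SlaterKosterTable`
objects. Sets are either parsed from a directory of ``{A}-{B}.skf`` files plus
a YAML sidecar, or generated synthetically from closed-form Slater-orbital
integrals.

The synthetic generator is fully deterministic. Its rules:

* S channels: analytic 1s/2p Slater two-center overlaps (:mod:`minidftb.slater`);
* H channels: the extended-Hueckel rule H = K * S * (eps_mu + eps_nu)/2 with
  the fixed constant K = 1.75;
* repulsive: a short-range exponential a*exp(-b*r)*(1 - r/rc)^3 sampled onto
  a cubic-spline block with an exponential head and a fifth-order tail that
  vanishes (with two derivatives) exactly at the cutoff rc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from . import slater
from .errors import CapabilityError, ConfigurationError
from .skf import (
    CHANNEL_INDEX,
    OnsiteBlock,
    RepulsiveSpline,
    SlaterKosterTable,
    read_skf,
    write_skf,
)

HUECKEL_K = 1.75  # fixed synthetic Hueckel constant; not user-tunable

L_NAMES = {0: "s", 1: "p", 2: "d"}


@dataclass
class Shell:
    l: int
    occupation: float
    energy: float          # on-site energy eps_l, hartree
    zeta: float = 0.0      # Slater exponent (synthetic sets only)

    @property
    def n_orbitals(self) -> int:
        return 2 * self.l + 1


@dataclass
class ElementSpec:
    """Per-element electronic parameters.

    ``hubbard_u`` / ``hubbard_derivative`` are per shell, aligned with
    ``shells``; the atom-resolved values (used by default in the SCC loop)
    are those of the highest occupied shell.
    """

    symbol: str
    shells: list[Shell]
    hubbard_u: list[float]
    hubbard_derivative: list[float]
    spin_constant: float = 0.0
    dipole_integral: float = 0.0       # on-site <s|r|p> integral D_A (a.u.)
    quadrupole_integral: float = 0.0   # on-site quadrupole integral Q_A (a.u.)
    dipole_scale: float = 1.0
    quadrupole_scale: float = 1.0
    born_radius: float = 2.0           # intrinsic Born radius rho_A, bohr
    hydrogen_class: bool = False       # triggers the damped gamma^h kernel

    def __post_init__(self) -> None:
        if len(self.hubbard_u) != len(self.shells):
            raise ConfigurationError(
                f"{self.symbol}: hubbard_u must have one entry per shell"
            )
        if len(self.hubbard_derivative) != len(self.shells):
            raise ConfigurationError(
                f"{self.symbol}: hubbard_derivative must have one entry per shell"
            )
        for u in self.hubbard_u:
            if u <= 0:
                raise ConfigurationError(f"{self.symbol}: Hubbard U must be positive")
        for sh in self.shells:
            if sh.occupation < 0:
                raise ConfigurationError(f"{self.symbol}: negative shell occupation")

    @property
    def n_orbitals(self) -> int:
        return sum(sh.n_orbitals for sh in self.shells)

    @property
    def valence_electrons(self) -> float:
        """Neutral-atom valence electron count q_A^0."""
        return sum(sh.occupation for sh in self.shells)

    @property
    def _highest_occupied_index(self) -> int:
        idx = [i for i, sh in enumerate(self.shells) if sh.occupation > 0]
        return idx[-1] if idx else len(self.shells) - 1

    @property
    def hubbard(self) -> float:
        """Atom-resolved Hubbard U (highest occupied shell)."""
        return self.hubbard_u[self._highest_occupied_index]

    @property
    def hubbard_d(self) -> float:
        """Atom-resolved Hubbard derivative U^d."""
        return self.hubbard_derivative[self._highest_occupied_index]


@dataclass
class ParameterSet:
    elements: dict[str, ElementSpec]
    tables: dict[tuple[str, str], SlaterKosterTable] = field(default_factory=dict)
    name: str = "parameter set"

    def element(self, symbol: str) -> ElementSpec:
        try:
            return self.elements[symbol]
        except KeyError:
            raise ConfigurationError(f"no parameters for element {symbol!r}") from None

    def table(self, e1: str, e2: str) -> SlaterKosterTable:
        try:
            return self.tables[(e1, e2)]
        except KeyError:
            raise ConfigurationError(
                f"no Slater-Koster table for the pair {e1}-{e2}"
            ) from None


# ----------------------------------------------------------- synthetic set

#: default synthetic element menu: X is a one-electron s element with
#: hydrogen-class gamma damping; Y is a six-electron s+p element.
DEFAULT_SYNTHETIC_MENU: dict[str, dict] = {
    "X": {
        "shells": [{"l": 0, "occupation": 1.0, "energy": -0.25, "zeta": 1.2}],
        "hubbard_u": [0.42],
        "hubbard_derivative": [-0.16],
        "spin_constant": -0.07,
        "born_radius": 1.6,
        "hydrogen_class": True,
    },
    "Y": {
        "shells": [
            {"l": 0, "occupation": 2.0, "energy": -0.60, "zeta": 1.6},
            {"l": 1, "occupation": 4.0, "energy": -0.26, "zeta": 1.3},
        ],
        "hubbard_u": [0.38, 0.36],
        "hubbard_derivative": [-0.14, -0.14],
        "spin_constant": -0.04,
        "born_radius": 2.4,
        "hydrogen_class": False,
    },
}

_REP_CUTOFF = 3.5        # bohr
_REP_AMPLITUDE = 0.10    # hartree scale, multiplied by sqrt(q0_A * q0_B)
_REP_DECAY = 2.0         # 1/bohr
_REP_FIRST_KNOT = 1.0    # bohr


def _onsite_dipole_integral(zeta_s: float, zeta_p: float) -> float:
    """Closed-form <1s(zs)|z|2p_z(zp)> for normalized Slater orbitals."""
    return 32.0 * (zeta_s ** 3 * zeta_p ** 5) ** 0.5 / (zeta_s + zeta_p) ** 5


def _onsite_quadrupole_integral(zeta_p: float) -> float:
    """On-site quadrupole integral Q_A = 3<r^2>_2p / 5 = 4.5 / zeta_p^2."""
    return 4.5 / zeta_p ** 2


def _synthetic_repulsive(a: float, b: float, rc: float) -> RepulsiveSpline:
    """Sample a*exp(-b r)(1-r/rc)^3 onto the skf spline representation."""

    def f(r):
        return a * np.exp(-b * r) * (1.0 - r / rc) ** 3

    def fp(r):
        return a * np.exp(-b * r) * (1.0 - r / rc) ** 2 * (
            -b * (1.0 - r / rc) - 3.0 / rc
        )

    knots = np.linspace(_REP_FIRST_KNOT, rc, 11)
    vals = f(knots)
    spl = CubicSpline(knots, vals, bc_type=((1, fp(knots[0])), (1, 0.0)))
    segments = []
    for k in range(len(knots) - 2):
        c = spl.c[:, k][::-1]  # ascending powers
        segments.append((float(knots[k]), float(knots[k + 1]), tuple(float(x) for x in c)))
    # final fifth-order segment: meet the cubic at its start, vanish with two
    # derivatives exactly at the cutoff
    t0, t1 = float(knots[-2]), float(knots[-1])
    h = t1 - t0
    v0 = float(spl(t0))
    d0 = float(spl(t0, 1))
    s0 = float(spl(t0, 2))
    c0, c1, c2 = v0, d0, 0.5 * s0
    # quintic q(x)=sum c_k x^k on x in [0,h] with q(h)=q'(h)=q''(h)=0
    A = np.array([
        [h ** 3, h ** 4, h ** 5],
        [3 * h ** 2, 4 * h ** 3, 5 * h ** 4],
        [6 * h, 12 * h ** 2, 20 * h ** 3],
    ])
    rhs = -np.array([
        c0 + c1 * h + c2 * h ** 2,
        c1 + 2 * c2 * h,
        2 * c2,
    ])
    c3, c4, c5 = np.linalg.solve(A, rhs)
    segments.append((t0, t1, (c0, c1, c2, float(c3), float(c4), float(c5))))

    # exponential head exp(-a1 r + a2) + a3 matching value/slope/curvature
    f0, d0h, s0h = f(knots[0]), fp(knots[0]), None
    eps = 1e-6
    s0h = (f(knots[0] + eps) - 2 * f0 + f(knots[0] - eps)) / eps ** 2
    a1 = -s0h / d0h if d0h != 0 else 1.0
    a2 = float(np.log(-d0h / a1) + a1 * knots[0]) if d0h < 0 and a1 > 0 else 0.0
    a3 = float(f0 - (-d0h / a1)) if d0h < 0 and a1 > 0 else float(f0)
    return RepulsiveSpline(cutoff=rc, head=(float(a1), a2, a3), segments=segments)


def make_synthetic_params(
    menu: dict[str, dict] | None = None,
    grid_spacing: float = 0.05,
    n_points: int = 240,
) -> ParameterSet:
    """Build the deterministic synthetic parameter set.

    Every pair of menu elements gets a Slater-Koster table; homonuclear
    tables carry the on-site block. Raises
    :class:`~minidftb.errors.CapabilityError` for shells with l > 1.
    """
    menu = DEFAULT_SYNTHETIC_MENU if menu is None else menu
    elements: dict[str, ElementSpec] = {}
    for sym, cfg in menu.items():
        shells = [Shell(**s) for s in cfg["shells"]]
        for sh in shells:
            if sh.l > 1:
                raise CapabilityError(
                    f"synthetic mode supports s and p shells only (element {sym})"
                )
        zeta_s = next((sh.zeta for sh in shells if sh.l == 0), 0.0)
        zeta_p = next((sh.zeta for sh in shells if sh.l == 1), 0.0)
        has_p = zeta_p > 0
        elements[sym] = ElementSpec(
            symbol=sym,
            shells=shells,
            hubbard_u=list(cfg["hubbard_u"]),
            hubbard_derivative=list(cfg["hubbard_derivative"]),
            spin_constant=cfg.get("spin_constant", 0.0),
            dipole_integral=(
                _onsite_dipole_integral(zeta_s, zeta_p) if has_p else 0.0
            ),
            quadrupole_integral=(
                _onsite_quadrupole_integral(zeta_p) if has_p else 0.0
            ),
            dipole_scale=cfg.get("dipole_scale", 1.0),
            quadrupole_scale=cfg.get("quadrupole_scale", 1.0),
            born_radius=cfg.get("born_radius", 2.0),
            hydrogen_class=cfg.get("hydrogen_class", False),
        )

    tables: dict[tuple[str, str], SlaterKosterTable] = {}
    syms = list(menu)
    for e1 in syms:
        for e2 in syms:
            tables[(e1, e2)] = _synthetic_table(
                elements[e1], elements[e2], grid_spacing, n_points
            )
    return ParameterSet(elements=elements, tables=tables, name="synthetic")


def _shell_by_l(spec: ElementSpec, l: int) -> Shell | None:
    for sh in spec.shells:
        if sh.l == l:
            return sh
    return None


def _synthetic_table(
    a: ElementSpec, b: ElementSpec, grid_spacing: float, n_points: int
) -> SlaterKosterTable:
    r_grid = grid_spacing * np.arange(1, n_points + 1)
    hs = np.zeros((n_points, 20))
    s_a, p_a = _shell_by_l(a, 0), _shell_by_l(a, 1)
    s_b, p_b = _shell_by_l(b, 0), _shell_by_l(b, 1)

    def fill(channel: str, sh1: Shell | None, sh2: Shell | None):
        if sh1 is None or sh2 is None:
            return
        col = CHANNEL_INDEX[channel]
        eavg = 0.5 * (sh1.energy + sh2.energy)
        for i, r in enumerate(r_grid):
            s = slater.sto_overlap(channel, sh1.zeta, sh2.zeta, float(r))
            hs[i, 10 + col] = s
            hs[i, col] = HUECKEL_K * s * eavg

    fill("sss", s_a, s_b)
    fill("sps", s_a, p_b)   # s on the first element, p on the second
    fill("pps", p_a, p_b)
    fill("ppp", p_a, p_b)

    onsite = None
    if a.symbol == b.symbol:
        energies = {"d": 0.0, "p": 0.0, "s": 0.0}
        hubbard = {"d": 0.0, "p": 0.0, "s": 0.0}
        occs = {"d": 0.0, "p": 0.0, "s": 0.0}
        for sh, u in zip(a.shells, a.hubbard_u):
            key = L_NAMES[sh.l]
            energies[key] = sh.energy
            hubbard[key] = u
            occs[key] = sh.occupation
        onsite = OnsiteBlock(energies=energies, spe=0.0, hubbard=hubbard,
                             occupations=occs)

    amp = _REP_AMPLITUDE * np.sqrt(a.valence_electrons * b.valence_electrons)
    repulsive = _synthetic_repulsive(amp, _REP_DECAY, _REP_CUTOFF)
    return SlaterKosterTable(
        grid_spacing=grid_spacing, n_points=n_points, hs=hs,
        mass=1.0, onsite=onsite, repulsive=repulsive,
        elements=(a.symbol, b.symbol),
    )


# ----------------------------------------------------------- directory I/O

SIDECAR_NAME = "electronic.yaml"


def save_parameter_set(pset: ParameterSet, directory) -> list[Path]:
    """Write {A}-{B}.skf files plus the electronic sidecar; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (e1, e2), table in sorted(pset.tables.items()):
        path = directory / f"{e1}-{e2}.skf"
        write_skf(path, table)
        written.append(path)
    side = {"name": pset.name, "elements": {}}
    for sym, el in sorted(pset.elements.items()):
        side["elements"][sym] = {
            "shells": [
                {"l": sh.l, "occupation": sh.occupation,
                 "energy": sh.energy, "zeta": sh.zeta}
                for sh in el.shells
            ],
            "hubbard_u": list(el.hubbard_u),
            "hubbard_derivative": list(el.hubbard_derivative),
            "spin_constant": el.spin_constant,
            "dipole_integral": el.dipole_integral,
            "quadrupole_integral": el.quadrupole_integral,
            "dipole_scale": el.dipole_scale,
            "quadrupole_scale": el.quadrupole_scale,
            "born_radius": el.born_radius,
            "hydrogen_class": el.hydrogen_class,
        }
    sidecar = directory / SIDECAR_NAME
    with open(sidecar, "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=True)
    written.append(sidecar)
    return written


def load_parameter_set(directory) -> ParameterSet:
    """Read a parameter directory ({A}-{B}.skf + YAML sidecar)."""
    directory = Path(directory)
    sidecar = directory / SIDECAR_NAME
    if not sidecar.exists():
        raise ConfigurationError(f"missing sidecar file {sidecar}")
    with open(sidecar) as fh:
        side = yaml.safe_load(fh)
    elements = {}
    for sym, cfg in side["elements"].items():
        elements[sym] = ElementSpec(
            symbol=sym,
            shells=[Shell(**s) for s in cfg["shells"]],
            hubbard_u=list(cfg["hubbard_u"]),
            hubbard_derivative=list(cfg["hubbard_derivative"]),
            spin_constant=cfg.get("spin_constant", 0.0),
            dipole_integral=cfg.get("dipole_integral", 0.0),
            quadrupole_integral=cfg.get("quadrupole_integral", 0.0),
            dipole_scale=cfg.get("dipole_scale", 1.0),
            quadrupole_scale=cfg.get("quadrupole_scale", 1.0),
            born_radius=cfg.get("born_radius", 2.0),
            hydrogen_class=cfg.get("hydrogen_class", False),
        )
    tables = {}
    for e1 in elements:
        for e2 in elements:
            path = directory / f"{e1}-{e2}.skf"
            if path.exists():
                tables[(e1, e2)] = read_skf(path, (e1, e2))
    return ParameterSet(elements=elements, tables=tables,
                        name=side.get("name", str(directory)))
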