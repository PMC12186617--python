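"""Molecular geometries and the XYZ / DFTB+ gen file formats.

Coordinates are stored in bohr internally; XYZ and gen files are in angstrom
(the conventions of both formats). Only non-periodic (cluster) geometries are
supported: gen files with the ``S`` or ``F`` flag are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParseError, UnsupportedFeatureError
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM


@dataclass
class Geometry:
    """An isolated molecule: element symbols + Cartesian positions (bohr)."""

    symbols: list[str]
    positions: np.ndarray  # (n_atoms, 3), bohr
    net_charge: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.symbols) == 0:
            raise GeometryError("geometry needs at least one atom")
        if len(self.symbols) != len(self.positions):
            raise GeometryError(
                f"{len(self.symbols)} symbols but {len(self.positions)} positions"
            )
        n = len(self.symbols)
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(self.positions[i] - self.positions[j]) <= 0.0:
                    raise GeometryError(f"atoms {i + 1} and {j + 1} coincide")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.positions[i] - self.positions[j]))

    def translated(self, shift) -> "Geometry":
        return Geometry(list(self.symbols), self.positions + np.asarray(shift),
                        self.net_charge, self.name)

    def rotated(self, rotation: np.ndarray) -> "Geometry":
        """Rigidly rotate all positions by a 3x3 rotation matrix."""
        return Geometry(list(self.symbols), self.positions @ np.asarray(rotation).T,
                        self.net_charge, self.name)


def read_xyz(path) -> Geometry:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: line 1 is not an atom count") from exc
    if len(lines) < n + 2:
        raise ParseError(f"{path}: header declares {n} atoms, file has fewer rows")
    symbols, coords = [], []
    for k, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {k + 3} has fewer than 4 fields")
        symbols.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {k + 3} has non-numeric coordinate") from exc
    name = lines[1].strip()
    return Geometry(symbols, np.array(coords) * BOHR_PER_ANGSTROM, name=name)


def write_xyz(path, geometry: Geometry, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n")
        fh.write((comment if comment is not None else geometry.name) + "\n")
        for sym, pos in zip(geometry.symbols, geometry.positions * ANGSTROM_PER_BOHR):
            fh.write(f"{sym:4s} {pos[0]:20.12f} {pos[1]:20.12f} {pos[2]:20.12f}\n")


def read_gen(path) -> Geometry:
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: truncated gen file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except ValueError as exc:
        raise ParseError(f"{path}: bad atom count on line 1") from exc
    flag = head[1].upper() if len(head) > 1 else "C"
    if flag in ("S", "F"):
        raise UnsupportedFeatureError(
            f"{path}: periodic gen geometry (flag {flag}) not supported; cluster only"
        )
    if flag != "C":
        raise ParseError(f"{path}: unknown gen flag {flag!r}")
    species = lines[1].split()
    if len(lines) < 2 + n:
        raise ParseError(f"{path}: header declares {n} atoms, file has fewer rows")
    symbols, coords = [], []
    for k, line in enumerate(lines[2:2 + n]):
        parts = line.split()
        if len(parts) < 5:
            raise ParseError(f"{path}: atom line {k + 1} has fewer than 5 fields")
        try:
            ispec = int(parts[1])
            xyz = [float(x) for x in parts[2:5]]
        except ValueError as exc:
            raise ParseError(f"{path}: atom line {k + 1} malformed") from exc
        if not 1 <= ispec <= len(species):
            raise ParseError(f"{path}: atom line {k + 1} references species {ispec}")
        symbols.append(species[ispec - 1])
        coords.append(xyz)
    return Geometry(symbols, np.array(coords) * BOHR_PER_ANGSTROM)


def write_gen(path, geometry: Geometry) -> None:
    species = sorted(set(geometry.symbols), key=geometry.symbols.index)
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms} C\n")
        fh.write(" ".join(species) + "\n")
        for i, (sym, pos) in enumerate(
            zip(geometry.symbols, geometry.positions * ANGSTROM_PER_BOHR), start=1
        ):
            fh.write(
                f"{i:5d} {species.index(sym) + 1:3d} "
                f"{pos[0]:20.12f} {pos[1]:20.12f} {pos[2]:20.12f}\n"
            )


def read_geometry(path, fmt: str | None = None) -> Geometry:
    """Read a geometry file, dispatching on the declared or inferred format."""
    if fmt is None:
        fmt = "gen" if str(path).endswith(".gen") else "xyz"
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "gen":
        return read_gen(path)
    raise ParseError(f"unknown geometry format {fmt!r}")
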