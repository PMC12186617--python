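"""Deterministic test fixtures: molecules, parameters, reference records.

The fixture molecules are calibration objects for the synthetic two-element
parameter set (X: one s electron, hydrogen-class; Y: six s+p electrons) and
do not emulate real chemistry:

* ``X2``   -- homonuclear s-dimer, bond 2.0 bohr
* ``XY``   -- heteronuclear diatomic, bond 2.2 bohr, net charge -1
             (8 electrons, clean closed shell)
* ``XY2``  -- bent "toy water": two X at 1.9 bohr from Y, angle 104 deg,
             8 electrons
* ``X3``   -- equilateral triangle, side 2.0 bohr
* ``X4``   -- centrosymmetric chain along z, spacing 2.0 bohr

Everything regenerates bit-identically; the only stochastic fixtures
(random coupling matrices, random unitaries) carry the explicit seed 20250606
recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .geometry import Geometry, write_gen, write_xyz
from .params import ParameterSet, make_synthetic_params, save_parameter_set

DEFAULT_SEED = 20250606

_XY2_BOND = 1.9          # bohr
_XY2_ANGLE = 104.0       # degrees


def geometry_x2() -> Geometry:
    return Geometry(["X", "X"], [[0, 0, 0], [0, 0, 2.0]], name="X2")


def geometry_xy() -> Geometry:
    # net charge -1 gives 8 valence electrons: a clean closed shell
    # (sigma^2 sigma^2 pi^4) with a non-degenerate sigma* LUMO
    return Geometry(["X", "Y"], [[0, 0, 0], [0, 0, 2.2]],
                    net_charge=-1.0, name="XY-")


def geometry_xy2() -> Geometry:
    half = np.deg2rad(_XY2_ANGLE / 2.0)
    x = _XY2_BOND * np.sin(half)
    z = _XY2_BOND * np.cos(half)
    return Geometry(
        ["Y", "X", "X"],
        [[0.0, 0.0, 0.0], [x, 0.0, z], [-x, 0.0, z]],
        name="XY2",
    )


def geometry_x3() -> Geometry:
    a = 2.0
    return Geometry(
        ["X", "X", "X"],
        [[0.0, 0.0, 0.0], [a, 0.0, 0.0], [a / 2, a * np.sqrt(3) / 2, 0.0]],
        name="X3",
    )


def geometry_x4() -> Geometry:
    return Geometry(
        ["X", "X", "X", "X"],
        [[0, 0, -3.0], [0, 0, -1.0], [0, 0, 1.0], [0, 0, 3.0]],
        name="X4",
    )


GEOMETRY_BUILDERS = {
    "X2": geometry_x2,
    "XY": geometry_xy,
    "XY2": geometry_xy2,
    "X3": geometry_x3,
    "X4": geometry_x4,
}


@dataclass
class FixtureSuite:
    geometries: dict[str, Geometry]
    params: ParameterSet
    seed: int = DEFAULT_SEED
    manifest: dict = field(default_factory=dict)

    def geometry(self, name: str) -> Geometry:
        try:
            return self.geometries[name]
        except KeyError:
            raise ConfigurationError(f"unknown fixture geometry {name!r}") from None


def build_suite(target_dir=None, seed: int = DEFAULT_SEED) -> FixtureSuite:
    """Build (and optionally write) the full fixture suite.

    When ``target_dir`` is given, XYZ + gen geometry files, the .skf
    parameter files with their sidecar, and a JSON manifest with SHA-256
    checksums are written there.
    """
    geometries = {name: fn() for name, fn in GEOMETRY_BUILDERS.items()}
    params = make_synthetic_params()
    suite = FixtureSuite(geometries=geometries, params=params, seed=seed)
    manifest: dict = {"seed": seed, "files": {}}
    if target_dir is not None:
        target = Path(target_dir)
        target.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, geom in geometries.items():
            p_xyz = target / f"{name}.xyz"
            p_gen = target / f"{name}.gen"
            write_xyz(p_xyz, geom)
            write_gen(p_gen, geom)
            written += [p_xyz, p_gen]
        written += save_parameter_set(params, target / "params")
        for p in written:
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            manifest["files"][str(p.relative_to(target))] = digest
        with open(target / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    suite.manifest = manifest
    return suite
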