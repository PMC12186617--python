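"""Hierarchical run configuration (YAML) and the high-level run dispatcher.

The configuration schema (all blocks optional unless a subcommand needs
them; units are declared per field):

.. code-block:: yaml

    model: dftb2            # dftb1 | dftb2 | dftb3
    params: synthetic       # 'synthetic' or a parameter-directory path
    temperature: 0.0        # electronic temperature, hartree
    charge: 0.0             # net molecular charge, e
    mixing:
      factor: 0.2
      anderson: false
    gamma:
      variant: gamma_h      # plain | gamma_h
      zeta: 4.0
    multipole:
      enabled: false
    constraints:            # atom indices are 1-based
      groups:
        - atoms: [1]
          target_population: 1.5   # or target_charge
      tolerance: 1.0e-6
    solvent:
      epsilon: 78.4
      kernel: still         # still | p16
      conductor: false
      alpb: true
      a_det: null           # bohr; derived when null
      radii: {}             # element -> intrinsic radius, bohr
    excited:
      n_states: 4
      method: rpa           # rpa | tda
      channel: singlet      # singlet | triplet
      x_c: 0

Atom indices are 1-based in every user-facing structure; energies are
reported in hartree with eV and kcal/mol conversions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version_placeholder  # noqa: F401
from .constraints import ConstraintSpec, solve_constrained
from .deltascf import delta_dftb
from .errors import ConfigurationError, MiniDFTBError
from .excited import excitation_spectrum
from .geometry import Geometry
from .params import ParameterSet, load_parameter_set, make_synthetic_params
from .scc import SCCOptions, scc_loop
from .solvation import SolvationModel
from .units import ANGSTROM_PER_BOHR, EV_PER_HARTREE, KCALMOL_PER_HARTREE


@dataclass
class RunConfig:
    model: str = "dftb2"
    params: str = "synthetic"
    temperature: float = 0.0
    charge: float | None = None
    mixing_factor: float = 0.2
    anderson: bool = False
    gamma_variant: str = "gamma_h"
    gamma_zeta: float = 4.0
    multipole: bool = False
    constraints: dict | None = None
    solvent: dict | None = None
    excited: dict = field(default_factory=lambda: {
        "n_states": 4, "method": "rpa", "channel": "singlet", "x_c": 0,
    })
    verbosity: int = 1

    def validate(self, task: str) -> None:
        if self.model not in ("dftb1", "dftb2", "dftb3"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if task == "constrain":
            if self.model == "dftb1":
                raise ConfigurationError(
                    "charge constraints require a self-consistent model "
                    "(dftb2 or dftb3), not dftb1"
                )
            if not self.constraints or not self.constraints.get("groups"):
                raise ConfigurationError("constrain task needs a constraints block")
        if task == "solvate" and not self.solvent:
            raise ConfigurationError("solvate task needs a solvent block")
        if self.excited.get("method") not in ("rpa", "tda"):
            raise ConfigurationError("excited method must be rpa or tda")
        if self.excited.get("channel") not in ("singlet", "triplet"):
            raise ConfigurationError("excited channel must be singlet or triplet")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig()
    cfg.model = raw.get("model", cfg.model)
    cfg.params = raw.get("params", cfg.params)
    cfg.temperature = float(raw.get("temperature", 0.0))
    if "charge" in raw:
        cfg.charge = float(raw["charge"])
    mix = raw.get("mixing", {}) or {}
    cfg.mixing_factor = float(mix.get("factor", 0.2))
    cfg.anderson = bool(mix.get("anderson", False))
    gam = raw.get("gamma", {}) or {}
    cfg.gamma_variant = gam.get("variant", "gamma_h")
    cfg.gamma_zeta = float(gam.get("zeta", 4.0))
    mp_block = raw.get("multipole", {}) or {}
    cfg.multipole = bool(mp_block.get("enabled", False)) \
        if isinstance(mp_block, dict) else bool(mp_block)
    cfg.constraints = raw.get("constraints")
    cfg.solvent = raw.get("solvent")
    if "excited" in raw and raw["excited"]:
        cfg.excited = {**cfg.excited, **raw["excited"]}
    cfg.verbosity = int(raw.get("verbosity", 1))
    return cfg


def resolve_params(spec: str) -> ParameterSet:
    if spec == "synthetic":
        return make_synthetic_params()
    return load_parameter_set(spec)


def scc_options_from_config(cfg: RunConfig, geometry: Geometry,
                            params: ParameterSet) -> SCCOptions:
    opts = SCCOptions(
        mixing=cfg.mixing_factor,
        anderson=cfg.anderson,
        kT=cfg.temperature,
        gamma_variant=cfg.gamma_variant,
        gamma_zeta=cfg.gamma_zeta,
        multipole=cfg.multipole,
    )
    if cfg.solvent:
        sv = cfg.solvent
        radii = sv.get("radii") or None
        opts.solvation = SolvationModel(
            epsilon=float(sv.get("epsilon", 78.4)),
            kernel=sv.get("kernel", "still"),
            conductor=bool(sv.get("conductor", False)),
            alpb=bool(sv.get("alpb", True)),
            a_det=sv.get("a_det"),
            intrinsic_radii=radii,
        )
    return opts


def constraint_spec_from_config(cfg: RunConfig, geometry: Geometry,
                                params: ParameterSet) -> ConstraintSpec:
    block = cfg.constraints or {}
    groups, targets = [], []
    for grp in block.get("groups", []):
        atoms = [int(a) - 1 for a in grp["atoms"]]   # 1-based in config
        for a in atoms:
            if not 0 <= a < geometry.n_atoms:
                raise ConfigurationError(f"constraint atom index {a + 1} out of range")
        if "target_population" in grp:
            tgt = float(grp["target_population"])
        elif "target_charge" in grp:
            q0 = sum(params.element(geometry.symbols[a]).valence_electrons
                     for a in atoms)
            tgt = q0 - float(grp["target_charge"])
        else:
            raise ConfigurationError(
                "constraint group needs target_population or target_charge"
            )
        groups.append(atoms)
        targets.append(tgt)
    return ConstraintSpec(
        groups=groups, targets=targets,
        lambdas=np.array([float(g.get("initial_lambda", 0.0))
                          for g in block.get("groups", [])]),
        tolerance=float(block.get("tolerance", 1e-6)),
    )


# ------------------------------------------------------------------ running

def _param_checksum(params: ParameterSet) -> str:
    h = hashlib.sha256()
    for key in sorted(params.tables):
        h.update(repr(key).encode())
        h.update(params.tables[key].hs.tobytes())
    return h.hexdigest()[:16]


def _energy_block(terms: dict) -> dict:
    out = {}
    for key, val in terms.items():
        if isinstance(val, dict):
            continue
        out[key] = {
            "hartree": float(val),
            "eV": float(val) * EV_PER_HARTREE,
            "kcal/mol": float(val) * KCALMOL_PER_HARTREE,
        }
    return out


def _charges_block(state, geometry, params) -> list:
    rows = []
    for a in range(geometry.n_atoms):
        rows.append({
            "atom": a + 1,
            "element": geometry.symbols[a],
            "position_angstrom": list(geometry.positions[a] * ANGSTROM_PER_BOHR),
            "dq_e": float(state.dq[a]),
            "partial_charge_e": float(-state.dq[a]),
        })
    return rows


def run(task: str, geometry: Geometry, cfg: RunConfig) -> tuple[dict, int]:
    """Dispatch a task; returns (results record, exit code)."""
    cfg.validate(task)
    params = resolve_params(cfg.params)
    if cfg.charge is not None:
        geometry.net_charge = cfg.charge
    opts = scc_options_from_config(cfg, geometry, params)
    record: dict = {
        "version": __import__("minidftb").__version__,
        "task": task,
        "model": cfg.model,
        "geometry_name": geometry.name,
        "net_charge": geometry.net_charge,
        "parameter_checksum": _param_checksum(params),
        "units": {"energy": "hartree (eV, kcal/mol echoed)",
                  "length": "angstrom in this record, bohr internally"},
    }
    exit_code = 1
    try:
        if task == "energy":
            state = scc_loop(geometry, params, cfg.model, opts)
            record["energy_terms"] = _energy_block(state.energy_terms)
            record["charges"] = _charges_block(state, geometry, params)
            record["converged"] = bool(state.converged)
            record["n_iterations"] = state.n_iterations
            if state.moments is not None:
                record["moments"] = {
                    "dipoles_au": state.moments.dd.tolist(),
                    "quadrupoles_au": state.moments.dQ.tolist(),
                }
            exit_code = 0 if state.converged else 2
        elif task == "solvate":
            state = scc_loop(geometry, params, cfg.model, opts)
            record["energy_terms"] = _energy_block(state.energy_terms)
            record["charges"] = _charges_block(state, geometry, params)
            record["converged"] = bool(state.converged)
            sv = opts.solvation
            record["solvent"] = {
                "epsilon": sv.epsilon, "kernel": sv.kernel,
                "born_radii_bohr": [float(x) for x in (sv.born_radii
                                                       if sv.born_radii is not None
                                                       else [])],
                "a_det_bohr": sv.a_det,
                "dG_diel_hartree": record["energy_terms"]["E_solv"]["hartree"],
            }
            exit_code = 0 if state.converged else 2
        elif task == "constrain":
            spec = constraint_spec_from_config(cfg, geometry, params)
            state, info = solve_constrained(geometry, params, cfg.model, spec, opts)
            record["energy_terms"] = _energy_block(state.energy_terms)
            record["charges"] = _charges_block(state, geometry, params)
            record["constraints"] = {
                "lambdas_hartree_per_e": [float(x) for x in info["lambdas"]],
                "residuals_e": [float(x) for x in info["residual"]],
                "free_energy_hartree": info["F"],
                "converged": bool(info["converged"]),
            }
            record["converged"] = bool(info["converged"] and state.converged)
            exit_code = 0 if record["converged"] else 2
        elif task == "excite":
            ex = cfg.excited
            ground, exc = excitation_spectrum(
                geometry, params, cfg.model,
                n_states=int(ex.get("n_states", 4)),
                method=ex.get("method", "rpa"),
                channel=ex.get("channel", "singlet"),
                options=opts, x_c=int(ex.get("x_c", 0)),
            )
            record["energy_terms"] = _energy_block(ground.energy_terms)
            record["converged"] = bool(ground.converged)
            states = []
            for i_s in range(len(exc.omegas)):
                dominant = int(np.argmax(np.abs(exc.xpy[i_s])))
                i_mo, a_mo = exc.pairs[dominant]
                states.append({
                    "state": i_s + 1,
                    "omega_hartree": float(exc.omegas[i_s]),
                    "omega_eV": float(exc.omegas[i_s]) * EV_PER_HARTREE,
                    "oscillator_strength": float(exc.oscillator_strengths[i_s]),
                    "dominant_transition": f"{i_mo + 1} -> {a_mo + 1}",
                    "norm": float(exc.xpy[i_s] @ exc.xmy[i_s]),
                })
            record["spectrum"] = {
                "method": exc.method, "channel": exc.channel, "states": states,
            }
            exit_code = 0 if ground.converged else 2
        elif task == "delta":
            res = delta_dftb(geometry, params, cfg.model, opts)
            record["delta_scf"] = {
                key: {"hartree": res[key], "eV": res[key] * EV_PER_HARTREE}
                for key in ("E_t", "E_m", "E_s")
            }
            record["energy_terms"] = _energy_block(res["ground"].energy_terms)
            record["excitation_energies_eV"] = {
                "triplet": (res["E_t"] - res["ground"].e_total) * EV_PER_HARTREE,
                "singlet": (res["E_s"] - res["ground"].e_total) * EV_PER_HARTREE,
            }
            record["converged"] = bool(res["converged"])
            exit_code = 0 if res["converged"] else 2
        else:
            raise ConfigurationError(f"unknown task {task!r}")
    except MiniDFTBError as exc:
        record["error"] = {"code": exc.code, "message": str(exc)}
        exit_code = 3
    return record, exit_code
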