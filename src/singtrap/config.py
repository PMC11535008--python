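"""Run-configuration parsing and columnar text output.

One YAML dialect is supported; unknown keys are rejected so that typos
fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .domains import DomainSpec
from .steady import Compartment, CompartmentConfiguration, ConfigurationError

_DOMAIN_KEYS = {"kind", "size", "D", "gamma0", "I0"}
_COMP_KEYS = {"center", "ell", "kappa", "model", "c0", "Dbar", "gbar", "Ibar"}
_SOLVER_KEYS = {"tolerance", "order", "rho_switch", "seed"}
_TOP_KEYS = {"domain", "epsilon", "separation_mult", "compartments", "solver"}


@dataclass
class SolverOptions:
    tolerance: float = 1e-10
    order: str = "two-term"
    rho_switch: float = 5.0
    seed: int = 0


@dataclass
class RunConfig:
    domain: dict
    epsilon: float
    compartments: list
    separation_mult: float = 10.0
    solver: SolverOptions = field(default_factory=SolverOptions)

    def configuration(self) -> CompartmentConfiguration:
        dom = DomainSpec(**self.domain)
        comps = []
        for c in self.compartments:
            c = dict(c)
            kappa = c.get("kappa", math.inf)
            if isinstance(kappa, str):
                if kappa.lower() not in ("inf", "infinity"):
                    raise ConfigurationError(
                        f"kappa must be a number or 'inf', got {kappa!r}")
                kappa = math.inf
            c["kappa"] = float(kappa)
            c["center"] = np.asarray(c["center"], dtype=float)
            comps.append(Compartment(**c))
        return CompartmentConfiguration(dom, self.epsilon, comps,
                                        separation_mult=self.separation_mult)

    def to_dict(self) -> dict:
        out = {
            "domain": dict(self.domain),
            "epsilon": self.epsilon,
            "separation_mult": self.separation_mult,
            "compartments": [dict(c) for c in self.compartments],
            "solver": {
                "tolerance": self.solver.tolerance,
                "order": self.solver.order,
                "rho_switch": self.solver.rho_switch,
                "seed": self.solver.seed,
            },
        }
        return out

    def digest(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _check_keys(block: dict, allowed: set, where: str):
    for k in block:
        if k not in allowed:
            raise ConfigurationError(
                f"unknown key {k!r} in {where}; expected one of {sorted(allowed)}"
            )


def parse_config_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a mapping")
    _check_keys(data, _TOP_KEYS, "top level")
    for req in ("domain", "epsilon", "compartments"):
        if req not in data:
            raise ConfigurationError(f"missing required key {req!r}")
    _check_keys(data["domain"], _DOMAIN_KEYS, "domain block")
    eps = float(data["epsilon"])
    if not (0.0 < eps < 1.0):
        raise ConfigurationError("epsilon must be in (0,1)")
    comps = data["compartments"]
    if not isinstance(comps, list) or not comps:
        raise ConfigurationError("compartments must be a non-empty list")
    for i, c in enumerate(comps):
        _check_keys(c, _COMP_KEYS, f"compartment {i}")
        if "center" not in c or "ell" not in c:
            raise ConfigurationError(f"compartment {i} needs 'center' and 'ell'")
    solver = SolverOptions()
    if "solver" in data:
        _check_keys(data["solver"], _SOLVER_KEYS, "solver block")
        for k, v in data["solver"].items():
            setattr(solver, k, type(getattr(solver, k))(v))
    rc = RunConfig(dict(data["domain"]), eps, [dict(c) for c in comps],
                   float(data.get("separation_mult", 10.0)), solver)
    rc.configuration()  # validate eagerly
    return rc


def parse_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config_dict(data)


def serialize_config(rc: RunConfig) -> str:
    return yaml.safe_dump(rc.to_dict(), sort_keys=True)


def write_table(records, path, columns=None) -> None:
    """Comma-separated columnar text with header and full double precision.

    Floats are written with repr so a read-back is bit-identical; record
    order and column order are deterministic.
    """
    records = list(records)
    if columns is None:
        if not records:
            raise ValueError("need explicit columns for an empty table")
        columns = list(records[0].keys())
    lines = [",".join(columns)]
    for rec in records:
        cells = []
        for c in columns:
            v = rec[c]
            cells.append(repr(float(v)) if isinstance(v, (float, np.floating))
                         else str(v))
        lines.append(",".join(cells))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_table(path):
    import pandas as pd

    return pd.read_csv(path)
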