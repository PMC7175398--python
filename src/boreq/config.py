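"""Configuration loading with unit normalization.

Model configurations come from YAML (or plain dicts). Physical quantities
may be given as plain SI numbers or as "value unit" strings (e.g.
``"80 mL/min"``, ``"16.8 C"``, ``"5 mm"``); everything is converted to SI
(m, K, Pa, m^3/s) on load. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .borehole_model import (
    AirflowSpec,
    BoreholeGeometry,
    SimulationConfig,
    SurfaceCase,
    SurfaceModelConfig,
    VaporParcel,
    VelocityConvention,
    XylemSource,
)
from .isotope_physics import Environment, P0, Species, saturation_mole_fraction

__all__ = [
    "parse_quantity",
    "parse_simulation_config",
    "load_simulation_config",
    "config_hash",
]

# unit -> (kind, factor or converter)
_LINEAR_UNITS = {
    "m": ("length", 1.0),
    "cm": ("length", 1e-2),
    "mm": ("length", 1e-3),
    "m3/s": ("flow", 1.0),
    "ml/min": ("flow", 1e-6 / 60.0),
    "l/min": ("flow", 1e-3 / 60.0),
    "pa": ("pressure", 1.0),
    "hpa": ("pressure", 100.0),
    "kpa": ("pressure", 1000.0),
    "k": ("temperature", None),
    "c": ("temperature", None),
}


def parse_quantity(value: Any, kind: str) -> float:
    """Normalize a number or a "value unit" string to SI.

    ``kind`` is one of length, flow, pressure, temperature; a bare number
    is taken to be already in SI units (K for temperature).
    """
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) != 2:
        raise ValueError(
            f"cannot parse quantity {value!r}; expected 'value unit'"
        )
    num = float(parts[0])
    unit = parts[1].lower().replace("°", "")
    if unit not in _LINEAR_UNITS:
        raise ValueError(f"unknown unit {parts[1]!r} in {value!r}")
    got_kind, factor = _LINEAR_UNITS[unit]
    if got_kind != kind:
        raise ValueError(
            f"unit {parts[1]!r} is a {got_kind} unit, expected {kind}"
        )
    if kind == "temperature":
        return num + 273.15 if unit == "c" else num
    return num * factor


def _check_keys(block: Mapping, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {name!r}; allowed: "
            f"{sorted(allowed)}"
        )


def parse_simulation_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a (possibly unit-ful) mapping.

    Expected blocks: geometry, flow, environment, inflow, xylem; optional:
    surface, N, kinetic_alpha.
    """
    _check_keys(
        cfg,
        {"geometry", "flow", "environment", "inflow", "xylem", "surface",
         "N", "kinetic_alpha"},
        "config",
    )

    g = cfg["geometry"]
    _check_keys(g, {"radius", "stem_diameter", "fitting_penetration",
                    "wetted_length"}, "geometry")
    geom = BoreholeGeometry(
        r=parse_quantity(g["radius"], "length"),
        stem_diameter=(
            parse_quantity(g["stem_diameter"], "length")
            if "stem_diameter" in g
            else None
        ),
        fitting_penetration=parse_quantity(
            g.get("fitting_penetration", 0.02), "length"
        ),
        wetted_length=(
            parse_quantity(g["wetted_length"], "length")
            if "wetted_length" in g
            else None
        ),
    )

    f = cfg["flow"]
    _check_keys(f, {"rate", "velocity_convention"}, "flow")
    flow = AirflowSpec(
        Q=parse_quantity(f["rate"], "flow"),
        velocity_convention=VelocityConvention(
            f.get("velocity_convention", "centerline_double")
        ),
    )

    e = cfg["environment"]
    _check_keys(e, {"temperature", "pressure"}, "environment")
    env = Environment(
        T=parse_quantity(e["temperature"], "temperature"),
        p=parse_quantity(e.get("pressure", P0), "pressure"),
    )

    i = cfg["inflow"]
    _check_keys(i, {"rh", "mole_fraction", "d18o", "d2h"}, "inflow")
    if "rh" in i and "mole_fraction" in i:
        raise ValueError("inflow: give either rh or mole_fraction, not both")
    if "rh" in i:
        w = float(i["rh"]) * saturation_mole_fraction(env.T, env.p)
    else:
        w = float(i["mole_fraction"])
    inflow = VaporParcel.from_deltas(
        w, {Species.O18: float(i["d18o"]), Species.H2: float(i["d2h"])}
    )

    x = cfg["xylem"]
    _check_keys(x, {"d18o", "d2h"}, "xylem")
    xylem = XylemSource.from_deltas(
        {Species.O18: float(x["d18o"]), Species.H2: float(x["d2h"])}
    )

    s = cfg.get("surface", {})
    _check_keys(s, {"case", "f"}, "surface")
    surface = SurfaceModelConfig(
        case=SurfaceCase(str(s.get("case", "3.1"))),
        f=float(s.get("f", 1.0)),
    )

    kin = cfg.get("kinetic_alpha")
    overrides = (
        {Species(k): float(v) for k, v in kin.items()} if kin else None
    )

    return SimulationConfig(
        geom=geom,
        flow=flow,
        env=env,
        inflow=inflow,
        xylem=xylem,
        surface=surface,
        N=int(cfg.get("N", 500)),
        kinetic_overrides=overrides,
    )


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML model configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return parse_simulation_config(data)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
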