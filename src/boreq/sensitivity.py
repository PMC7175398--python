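"""Parameter sweeps over the borehole model and the minimum-mixing search.

Sweeps vary one driver at a time -- flow rate, stem diameter, inflow
humidity, or the surface mixing fraction -- and evaluate the outlet isotopic
composition under the selected surface closures, alongside two reference
lines: the liquid stem water itself and vapor in isotopic equilibrium with
it. ``find_min_mixing_fraction`` locates the smallest xylem fraction f at
which the mixed closure becomes indistinguishable (within a stated per-mil
tolerance) from full xylem equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .borehole_model import (
    AirflowSpec,
    SimulationConfig,
    SurfaceCase,
    SurfaceModelConfig,
    VaporParcel,
)
from .isotope_physics import (
    Species,
    ratio_to_delta,
    saturation_mole_fraction,
)

__all__ = [
    "SweepSpec",
    "run_sweep",
    "MixingSearchResult",
    "find_min_mixing_fraction",
    "default_flow_grid",
]

_VARIABLES = ("flow", "diameter", "inflow_rh", "mixing_fraction")


def default_flow_grid(
    q_min_ml_min: float = 40.0, q_max_ml_min: float = 400.0, n: int = 11
) -> list[float]:
    """Log-spaced flow grid in mL/min (flow responses are ratio-like)."""
    return list(np.geomspace(q_min_ml_min, q_max_ml_min, n))


@dataclass(frozen=True)
class SweepSpec:
    """One-variable sweep: which driver, over which grid, from which base.

    Grid units: flow in mL/min, diameter in m, inflow_rh as a fraction of
    saturation at stem temperature, mixing_fraction dimensionless in [0, 1].
    """

    variable: str
    grid: Sequence[float]
    base: SimulationConfig
    cases: Sequence[SurfaceCase] = (
        SurfaceCase.XYLEM_EQUILIBRIUM,
        SurfaceCase.CRAIG_GORDON,
        SurfaceCase.MIXED,
    )

    def __post_init__(self) -> None:
        if self.variable not in _VARIABLES:
            raise ValueError(
                f"unknown sweep variable {self.variable!r}; expected one of "
                f"{_VARIABLES}"
            )
        grid = list(self.grid)
        if not grid:
            raise ValueError("sweep grid must be non-empty")
        diffs = np.diff(grid)
        if len(grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sweep grid must be strictly monotone")


def _apply(base: SimulationConfig, variable: str, value: float) -> SimulationConfig:
    if variable == "flow":
        return base.with_updates(
            flow=AirflowSpec.from_ml_per_min(
                value, base.flow.velocity_convention
            )
        )
    if variable == "diameter":
        # Fig-6-style sweeps treat the full traversed stem diameter as the
        # wetted length; the fitting subtraction is an experimental-geometry
        # convention, not part of the idealized model.
        return base.with_updates(geom=replace(base.geom, stem_diameter=value,
                                              wetted_length=value))
    if variable == "inflow_rh":
        w_sat = saturation_mole_fraction(base.env.T, base.env.p)
        return base.with_updates(
            inflow=VaporParcel(w=value * w_sat, R=dict(base.inflow.R))
        )
    if variable == "mixing_fraction":
        return base.with_updates(
            surface=SurfaceModelConfig(case=SurfaceCase.MIXED, f=value)
        )
    raise AssertionError(variable)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; one row per (grid value, case).

    Columns: the swept variable and value, the case label, outlet delta per
    species, outlet relative humidity, and the two reference lines (liquid
    stem water delta and the equilibrium-vapor delta) per species. Rows
    whose simulation fails carry the error message in ``error`` and NaN
    outputs; the sweep continues.
    """
    rows = []
    for value in spec.grid:
        for case in spec.cases:
            case = SurfaceCase(case)
            cfg = _apply(spec.base, spec.variable, value)
            if spec.variable != "mixing_fraction":
                cfg = cfg.with_updates(
                    surface=SurfaceModelConfig(case=case, f=cfg.surface.f)
                )
            row: dict = {
                "variable": spec.variable,
                "value": value,
                "case": case.value,
            }
            alphas = cfg.fractionation()
            for s in Species:
                if s in cfg.xylem.R_x:
                    row[f"stem_water_delta_{s.value.lower()}"] = (
                        cfg.xylem.delta(s)
                    )
                    row[f"equilibrium_delta_{s.value.lower()}"] = ratio_to_delta(
                        cfg.xylem.R_x[s] / alphas.alpha_plus[s]
                    )
            try:
                res = cfg.run()
            except (ValueError, ZeroDivisionError) as exc:
                row["error"] = str(exc)
                rows.append(row)
                continue
            row["error"] = ""
            row["outlet_h"] = res.outlet_h
            for s in res.outlet.R:
                row[f"outlet_delta_{s.value.lower()}"] = res.outlet_delta(s)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MixingSearchResult:
    """Smallest xylem fraction f matching the xylem-equilibrium outlet."""

    fraction: float | None
    tolerance_permil: float
    deviation_permil: float
    species: Species
    found: bool


def find_min_mixing_fraction(
    base: SimulationConfig,
    tolerance_permil: float = 0.5,
    species: Species = Species.O18,
    resolution: float = 1e-4,
) -> MixingSearchResult:
    """Smallest f for which |outlet delta(f) - outlet delta(case 3.1)| <= tol.

    The mixed-closure outlet moves monotonically from the Craig-Gordon value
    at f=0 to the xylem-equilibrium value at f=1, so a bisection on f is
    valid; the search refines to ``resolution`` in f and returns a
    conservative (upper) bracket endpoint.
    """
    if tolerance_permil <= 0:
        raise ValueError("tolerance must be positive")
    species = Species(species)

    target = (
        base.with_updates(
            surface=SurfaceModelConfig(case=SurfaceCase.XYLEM_EQUILIBRIUM)
        )
        .run()
        .outlet_delta(species)
    )

    def deviation(f: float) -> float:
        res = base.with_updates(
            surface=SurfaceModelConfig(case=SurfaceCase.MIXED, f=f)
        ).run()
        return abs(res.outlet_delta(species) - target)

    if deviation(0.0) <= tolerance_permil:
        return MixingSearchResult(0.0, tolerance_permil, deviation(0.0),
                                  species, True)
    if deviation(1.0) > tolerance_permil:
        return MixingSearchResult(None, tolerance_permil, deviation(1.0),
                                  species, False)

    lo, hi = 0.0, 1.0  # deviation(lo) > tol >= deviation(hi)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if deviation(mid) <= tolerance_permil:
            hi = mid
        else:
            lo = mid
    return MixingSearchResult(hi, tolerance_permil, deviation(hi), species, True)
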