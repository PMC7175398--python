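"""Where the borehole method works and where it fails.

Sweeps flow rate and stem diameter under the three surface-water closures
and finds the minimum xylem-mixing fraction at which the mixed closure
becomes indistinguishable from full equilibrium with xylem water.
"""

import numpy as np

from boreq import (
    AirflowSpec,
    BoreholeGeometry,
    Environment,
    SimulationConfig,
    Species,
    SurfaceCase,
    SurfaceModelConfig,
    SweepSpec,
    VaporParcel,
    XylemSource,
    find_min_mixing_fraction,
    run_sweep,
    saturation_mole_fraction,
)
from boreq.sensitivity import default_flow_grid

env = Environment(T=283.15)
w_sat = saturation_mole_fraction(env.T, env.p)
base = SimulationConfig(
    geom=BoreholeGeometry(r=0.005, wetted_length=0.10),
    flow=AirflowSpec.from_ml_per_min(40.0),
    env=env,
    inflow=VaporParcel.from_deltas(
        0.5 * w_sat, {Species.O18: -20.0, Species.H2: -150.0}
    ),
    xylem=XylemSource.from_deltas({Species.O18: -15.0, Species.H2: -110.0}),
    # mixed closure: 35% of the surface film renewed by xylem water
    surface=SurfaceModelConfig(case=SurfaceCase.XYLEM_EQUILIBRIUM, f=0.35),
)

flow = run_sweep(SweepSpec("flow", default_flow_grid(40, 400, 5), base))
print("flow sweep (outlet d18O, permil):")
print(
    flow.pivot(index="value", columns="case", values="outlet_delta_o18")
    .to_string(float_format=lambda v: f"{v:.2f}")
)
print()

dia = run_sweep(SweepSpec("diameter", list(np.arange(0.03, 0.16, 0.03)), base))
print("stem-diameter sweep (outlet d18O, permil):")
print(
    dia.pivot(index="value", columns="case", values="outlet_delta_o18")
    .to_string(float_format=lambda v: f"{v:.2f}")
)
print()

res = find_min_mixing_fraction(base, tolerance_permil=0.5)
print(
    f"minimum xylem mixing fraction f = {res.fraction:.3f} "
    f"(tolerance {res.tolerance_permil} permil, "
    f"deviation {res.deviation_permil:.3f} permil)"
)
print()
print(
    "Case 3.1 (wall water = xylem) tracks the equilibrium value across all\n"
    "flows and diameters above ~5 cm; the Craig-Gordon closure (3.2) sits\n"
    "several permil heavier and barely responds to flow. Modest renewal of\n"
    "the surface film by xylem water (f above the printed minimum) already\n"
    "pulls the outflow onto the equilibrium line."
)
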