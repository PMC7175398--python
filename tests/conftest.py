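import pytest

from boreq import (
    AirflowSpec,
    BoreholeGeometry,
    Environment,
    SimulationConfig,
    Species,
    SurfaceCase,
    SurfaceModelConfig,
    VaporParcel,
    XylemSource,
    saturation_mole_fraction,
)


@pytest.fixture
def env_10c() -> Environment:
    """Borehole conditions of the modeling walkthrough: 10 degC, 1 atm."""
    return Environment(T=283.15)


@pytest.fixture
def modeling_config(env_10c) -> SimulationConfig:
    """The modeling scenario: 10 mm borehole, 0.10 m wetted length,
    40 mL/min, xylem water at -15 permil d18O, inflow vapor -20 permil at
    50% relative humidity."""
    w_sat = saturation_mole_fraction(env_10c.T, env_10c.p)
    return SimulationConfig(
        geom=BoreholeGeometry(r=0.005, wetted_length=0.10),
        flow=AirflowSpec.from_ml_per_min(40.0),
        env=env_10c,
        inflow=VaporParcel.from_deltas(
            0.5 * w_sat, {Species.O18: -20.0, Species.H2: -150.0}
        ),
        xylem=XylemSource.from_deltas({Species.O18: -15.0, Species.H2: -110.0}),
        surface=SurfaceModelConfig(case=SurfaceCase.XYLEM_EQUILIBRIUM),
        N=500,
    )
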