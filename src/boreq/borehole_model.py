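"""Segmented advection-diffusion model of borehole equilibration.

Air flows through a borehole drilled through a tree stem. Along the flow
path it takes up water vapor evaporating from the wetted borehole wall and
exchanges isotopically with the liquid xylem water behind the wall. The
borehole is discretized into N segments along the flow path; each segment is
treated as well mixed, the outflow of one segment being the inflow of the
next, which approaches the continuous solution for large N.

Per segment, the vapor mole fraction relaxes toward a steady state that is a
weighted mean of the incoming mole fraction and the saturation mole fraction
at stem temperature, the weights being the carrier flow and the wall-exchange
conductance. The isotopic composition of the outflow depends on the assumed
composition of the water film at the borehole surface, with three closures:

* ``XYLEM_EQUILIBRIUM`` -- the surface stays at the xylem composition
  (R_s = R_x / alpha+): the xylem pool is so large that exchange cannot
  shift it.
* ``CRAIG_GORDON`` -- the surface film reaches the evaporative steady state
  in which the net evaporated flux carries the xylem (supply) composition,
  as in Craig-Gordon leaf-water enrichment.
* ``MIXED`` -- the surface is a fraction f of xylem-equilibrium water and
  (1-f) of Craig-Gordon steady-state water; f=1 and f=0 recover the two
  pure closures exactly.

All flows are handled volumetrically (m^3/s at borehole conditions); the
governing balances are homogeneous in 1/V_1mol so molar and volumetric
formulations coincide. Condensation (vapor above saturation) is treated as
an error state, not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

from .isotope_physics import (
    Environment,
    FractionationSet,
    Species,
    delta_to_ratio,
    molar_volume,
    ratio_to_delta,
    saturation_mole_fraction,
    vapor_diffusivity,
)

__all__ = [
    "VelocityConvention",
    "SurfaceCase",
    "BoreholeGeometry",
    "AirflowSpec",
    "VaporParcel",
    "XylemSource",
    "SurfaceModelConfig",
    "TimeConstants",
    "SegmentState",
    "SimulationResult",
    "SimulationConfig",
    "diffusion_time",
    "turnover_time",
    "vapor_time_constant",
    "isotope_time_constants",
    "segment_vapor_steady_state",
    "segment_vapor_step",
    "segment_isotope_step",
    "surface_composition",
    "segment_isotope_steady_state",
    "dry_air_inflow_correction",
    "simulate_borehole",
]


class VelocityConvention(str, Enum):
    """How the effective carrier flow relates to the measured volumetric flow.

    Laminar pipe flow has a parabolic profile whose centerline velocity is
    twice the mean; ``CENTERLINE_DOUBLE`` doubles the measured flow to
    represent the moving core, ``MEAN`` uses the measured flow as is.
    """

    CENTERLINE_DOUBLE = "centerline_double"
    MEAN = "mean"


class SurfaceCase(str, Enum):
    """Closure for the isotopic composition of the borehole surface water."""

    XYLEM_EQUILIBRIUM = "3.1"
    CRAIG_GORDON = "3.2"
    MIXED = "3.3"


@dataclass(frozen=True)
class BoreholeGeometry:
    """Borehole radius, stem diameter and derived wetted geometry.

    The wetted length defaults to ``stem_diameter - fitting_penetration``:
    the tube fittings at each end penetrate the stem (about 1 cm per side)
    and block wall contact there. Pass ``wetted_length`` to override.
    """

    r: float
    stem_diameter: float | None = None
    fitting_penetration: float = 0.02
    wetted_length: float | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"borehole radius must be positive (got {self.r})")
        if self.l <= 0:
            raise ValueError(
                f"wetted length must be positive (got {self.l}); check stem "
                "diameter against fitting penetration"
            )

    @property
    def l(self) -> float:
        """Wetted borehole length (m)."""
        if self.wetted_length is not None:
            return self.wetted_length
        if self.stem_diameter is None:
            raise ValueError("need stem_diameter or wetted_length")
        return self.stem_diameter - self.fitting_penetration

    @property
    def volume(self) -> float:
        """Borehole air volume V = pi r^2 l (m^3)."""
        return math.pi * self.r**2 * self.l

    @property
    def wall_area(self) -> float:
        """Wetted wall area A = 2 pi r l (m^2); note A/r = 2 pi l."""
        return 2.0 * math.pi * self.r * self.l


@dataclass(frozen=True)
class AirflowSpec:
    """Volumetric air flow through the borehole.

    ``Q`` is the measured (mean) volumetric flow in m^3/s; use
    :func:`AirflowSpec.from_ml_per_min` for instrument units. The
    ``velocity_convention`` selects the effective carrier flow used in the
    advective terms (see :class:`VelocityConvention`).
    """

    Q: float
    velocity_convention: VelocityConvention = VelocityConvention.CENTERLINE_DOUBLE

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError(f"flow rate must be positive (got {self.Q})")

    @classmethod
    def from_ml_per_min(
        cls,
        q_ml_min: float,
        velocity_convention: VelocityConvention = VelocityConvention.CENTERLINE_DOUBLE,
    ) -> "AirflowSpec":
        return cls(Q=q_ml_min * 1e-6 / 60.0, velocity_convention=velocity_convention)

    def carrier_flow(
        self, convention: VelocityConvention | None = None
    ) -> float:
        """Effective carrier flow (m^3/s) under the given convention."""
        conv = VelocityConvention(convention or self.velocity_convention)
        if conv is VelocityConvention.CENTERLINE_DOUBLE:
            return 2.0 * self.Q
        return self.Q

    def molar_mean_flow(self, env: Environment) -> float:
        """Measured mean flow expressed in mol/s at the given conditions."""
        return self.Q / molar_volume(env)


@dataclass(frozen=True)
class VaporParcel:
    """An air parcel: water-vapor mole fraction w and per-species ratio R."""

    w: float
    R: dict[Species, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.w < 1.0:
            raise ValueError(f"mole fraction must be in [0, 1) (got {self.w})")
        for s, r in self.R.items():
            if r <= 0:
                raise ValueError(f"ratio for {s} must be positive (got {r})")

    @classmethod
    def from_deltas(cls, w: float, deltas: dict[Species, float]) -> "VaporParcel":
        return cls(w=w, R={Species(s): delta_to_ratio(d) for s, d in deltas.items()})

    def delta(self, species: Species) -> float:
        return ratio_to_delta(self.R[Species(species)])


@dataclass(frozen=True)
class XylemSource:
    """Liquid xylem water isotopic composition (VSMOW-normalized ratios)."""

    R_x: dict[Species, float]

    @classmethod
    def from_deltas(cls, deltas: dict[Species, float]) -> "XylemSource":
        return cls(R_x={Species(s): delta_to_ratio(d) for s, d in deltas.items()})

    def delta(self, species: Species) -> float:
        return ratio_to_delta(self.R_x[Species(species)])


@dataclass(frozen=True)
class SurfaceModelConfig:
    """Surface-water closure: the case and, for MIXED, the xylem fraction f."""

    case: SurfaceCase = SurfaceCase.XYLEM_EQUILIBRIUM
    f: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"mixing fraction f must be in [0, 1] (got {self.f})")


@dataclass(frozen=True)
class TimeConstants:
    """Characteristic times of borehole equilibration (s).

    t_d: radial diffusion to/from the wall, r^2/(4D).
    t_u: borehole turnover by the air stream.
    t_w: relaxation of the vapor mole fraction.
    t_x_x: relaxation of the isotope ratio under the xylem-equilibrium
        closure (>= t_w, equal iff alpha_k = 1).
    t_x_C: relaxation of the isotope ratio under the Craig-Gordon closure.
    """

    t_d: float
    t_u: float
    t_w: float
    t_x_x: dict[Species, float] | None = None
    t_x_C: float | None = None


def diffusion_time(geom: BoreholeGeometry, env: Environment) -> float:
    """Maximum radial diffusion time t_d = r^2 / (4 D) in seconds."""
    return geom.r**2 / (4.0 * vapor_diffusivity(env))


def turnover_time(
    geom: BoreholeGeometry,
    flow: AirflowSpec,
    convention: VelocityConvention | None = None,
) -> float:
    """Borehole turnover time t_u = V / carrier flow in seconds.

    The default (the flow spec's convention, centerline doubling unless
    overridden) gives t_u = pi r^2 l / (2 Q): the moving core of the
    parabolic profile turns the volume over twice as fast as the mean flow.
    """
    return geom.volume / flow.carrier_flow(convention)


def _wall_conductance(geom: BoreholeGeometry, env: Environment) -> float:
    """Volumetric wall-exchange conductance (A/r) * D = 2 pi l D, m^3/s."""
    return 2.0 * math.pi * geom.l * vapor_diffusivity(env)


def vapor_time_constant(
    geom: BoreholeGeometry,
    flow: AirflowSpec,
    env: Environment,
    convention: VelocityConvention = VelocityConvention.MEAN,
) -> float:
    """Vapor mole-fraction time constant t_w = V / (Q_eff + 2 pi l D).

    Defaults to the mean-flow convention: the relaxation of the bulk vapor
    content is governed by the measured throughflow, not the centerline
    core. In the Q -> 0 limit t_w -> r^2/(2D).
    """
    q = flow.carrier_flow(convention)
    return geom.volume / (q + _wall_conductance(geom, env))


def isotope_time_constants(
    geom: BoreholeGeometry,
    flow: AirflowSpec,
    env: Environment,
    w_in: float,
    alphas: FractionationSet | None = None,
    convention: VelocityConvention = VelocityConvention.MEAN,
) -> TimeConstants:
    """Whole-borehole time constants including the isotopic ones.

    ``w_in`` is the inflow vapor mole fraction; the outflow mole fraction is
    taken at its steady state. Under the xylem-equilibrium closure,
    t_x_x = V w_o / (Q_eff w_i + 2 pi l D [w_sat - (1 - 1/alpha_k) w_o])
    which satisfies t_x_x >= t_w with equality iff alpha_k = 1. Under the
    Craig-Gordon closure the wall term is the net evaporation flux only:
    t_x_C = V w_o / (Q_eff w_i + 2 pi l (D/r) r (w_sat - w_o)).
    """
    alphas = alphas or FractionationSet.at_temperature(env.T)
    w_sat = saturation_mole_fraction(env.T, env.p)
    if w_in > w_sat:
        raise ValueError(
            f"inflow vapor (w={w_in:.4g}) exceeds saturation "
            f"(w_sat={w_sat:.4g}): condensation regime is not modeled"
        )
    q = flow.carrier_flow(convention)
    g = _wall_conductance(geom, env)
    V = geom.volume
    w_o = (q * w_in + g * w_sat) / (q + g)

    t_x_x = {}
    for s, a_k in alphas.alpha_k.items():
        denom = q * w_in + g * (w_sat - (1.0 - 1.0 / a_k) * w_o)
        t_x_x[s] = V * w_o / denom
    evap = g * (w_sat - w_o)
    denom_c = q * w_in + evap
    t_x_C = V * w_o / denom_c if denom_c > 0 else math.inf

    return TimeConstants(
        t_d=diffusion_time(geom, env),
        t_u=turnover_time(geom, flow),
        t_w=vapor_time_constant(geom, flow, env, convention),
        t_x_x=t_x_x,
        t_x_C=t_x_C,
    )


def segment_vapor_steady_state(
    w_in: float,
    seg_length: float,
    flow: AirflowSpec,
    env: Environment,
    convention: VelocityConvention | None = None,
) -> float:
    """Steady-state outflow mole fraction of one segment.

    Weighted mean of the incoming mole fraction and the saturation mole
    fraction, weighted by carrier flow and wall conductance 2 pi l_seg D
    (independent of the borehole radius since A/r = 2 pi l).
    """
    if not 0.0 <= w_in < 1.0:
        raise ValueError(f"mole fraction must be in [0, 1) (got {w_in})")
    q = flow.carrier_flow(convention)
    g = 2.0 * math.pi * seg_length * vapor_diffusivity(env)
    w_sat = saturation_mole_fraction(env.T, env.p)
    return (q * w_in + g * w_sat) / (q + g)


def segment_vapor_step(
    w_t: float, dt: float, steady_state: float, t_w: float
) -> float:
    """Non-steady-state update: exponential relaxation toward steady state."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative (got {dt})")
    return steady_state + (w_t - steady_state) * math.exp(-dt / t_w)


# The isotopic relaxation kernel has the same exponential form.
segment_isotope_step = segment_vapor_step


def surface_composition(
    config: SurfaceModelConfig,
    xylem: XylemSource,
    parcel: VaporParcel,
    env: Environment,
    alphas: FractionationSet | None = None,
) -> dict[Species, float]:
    """Vapor-side surface composition R_s per species for a given air parcel.

    * xylem equilibrium: R_s = R_x / alpha+.
    * Craig-Gordon: R_s solves (w_sat R_s - w_o R_o)/alpha_k =
      (w_sat - w_o) R_x, i.e. the net evaporated flux carries the xylem
      composition. At w_o = w_sat (no net evaporation) the exchange
      equilibrium with the borehole vapor, R_s = R_o, is returned.
    * mixed: f-weighted combination of the two.
    """
    alphas = alphas or FractionationSet.at_temperature(env.T)
    w_sat = saturation_mole_fraction(env.T, env.p)
    w_o = parcel.w
    if w_o > w_sat:
        raise ValueError(
            f"parcel above saturation (w={w_o:.4g} > w_sat={w_sat:.4g})"
        )

    out: dict[Species, float] = {}
    for s in parcel.R:
        r_eq = xylem.R_x[s] / alphas.alpha_plus[s]
        if w_o >= w_sat:
            r_cg = parcel.R[s]
        else:
            r_cg = (
                alphas.alpha_k[s] * (w_sat - w_o) * xylem.R_x[s]
                + w_o * parcel.R[s]
            ) / w_sat
        if config.case is SurfaceCase.XYLEM_EQUILIBRIUM:
            out[s] = r_eq
        elif config.case is SurfaceCase.CRAIG_GORDON:
            out[s] = r_cg
        else:
            out[s] = config.f * r_eq + (1.0 - config.f) * r_cg
    return out


def segment_isotope_steady_state(
    config: SurfaceModelConfig,
    w_in: float,
    R_in: dict[Species, float],
    w_out: float,
    xylem: XylemSource,
    seg_length: float,
    flow: AirflowSpec,
    env: Environment,
    alphas: FractionationSet | None = None,
    convention: VelocityConvention | None = None,
) -> dict[Species, float]:
    """Steady-state outflow isotope ratio of one segment, per species.

    ``w_out`` must be the segment's steady-state mole fraction (from
    :func:`segment_vapor_steady_state`); the closures are evaluated at that
    vapor state.
    """
    alphas = alphas or FractionationSet.at_temperature(env.T)
    q = flow.carrier_flow(convention)
    g = 2.0 * math.pi * seg_length * vapor_diffusivity(env)
    w_sat = saturation_mole_fraction(env.T, env.p)
    evap = g * (w_sat - w_out)  # net volumetric vapor source from the wall

    case = config.case
    f = config.f
    # MIXED endpoints dispatch to the pure closures so f=0 and f=1 reproduce
    # them bit-for-bit.
    if case is SurfaceCase.MIXED:
        if f == 1.0:
            case = SurfaceCase.XYLEM_EQUILIBRIUM
        elif f == 0.0:
            case = SurfaceCase.CRAIG_GORDON

    out: dict[Species, float] = {}
    for s, R_i in R_in.items():
        R_x = xylem.R_x[s]
        a_plus = alphas.alpha_plus[s]
        a_k = alphas.alpha_k[s]
        if case is SurfaceCase.XYLEM_EQUILIBRIUM:
            num = q * w_in * R_i + (g / a_k) * w_sat * R_x / a_plus
            den = q * w_in + g * (w_sat - (1.0 - 1.0 / a_k) * w_out)
        elif case is SurfaceCase.CRAIG_GORDON:
            num = q * w_in * R_i + evap * R_x
            den = q * w_in + evap
        else:
            # Joint linear fixed point of the isotope balance
            #   q w_i R_i - q w_o R_o + (g/a_k)(w_sat R_s - w_o R_o) = 0
            # with the f-mixture surface closure substituted for R_s.
            num = (
                q * w_in * R_i
                + (g / a_k) * f * w_sat * R_x / a_plus
                + (1.0 - f) * evap * R_x
            )
            den = q * w_out + f * (g / a_k) * w_out
        if den <= 0.0:
            raise ZeroDivisionError(
                "degenerate segment: no flow and no wall exchange"
            )
        out[s] = num / den
    return out


def dry_air_inflow_correction(u_o: float, w_in: float, w_out: float) -> float:
    """Inflow rate u_i = u_o (1 - w_o)/(1 - w_i) when u_o is a moist-air flow.

    The segment chain itself assumes u_i = u_o; this correction is for users
    whose flow controller meters dry air upstream of the borehole.
    """
    if not (0.0 <= w_in < 1.0 and 0.0 <= w_out < 1.0):
        raise ValueError("mole fractions must be in [0, 1)")
    return u_o * (1.0 - w_out) / (1.0 - w_in)


@dataclass(frozen=True)
class SegmentState:
    """State at the downstream face of one segment."""

    position: float  # distance from inlet to segment outlet (m)
    w: float
    h: float
    R: dict[Species, float]

    def delta(self, species: Species) -> float:
        return ratio_to_delta(self.R[Species(species)])


@dataclass(frozen=True)
class SimulationResult:
    """Per-segment profile and outlet state of a borehole run."""

    segments: list[SegmentState]
    outlet: VaporParcel
    outlet_h: float
    N: int
    evaporation_total: float  # net molar water flux added along the bore (mol/s)
    time_constants: TimeConstants

    def outlet_delta(self, species: Species) -> float:
        return self.outlet.delta(species)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-segment table (one row per segment)."""
        rows = []
        for i, seg in enumerate(self.segments, start=1):
            row = {"segment": i, "position_m": seg.position, "w": seg.w, "h": seg.h}
            for s in seg.R:
                row[f"delta_{s.value.lower()}_permil"] = seg.delta(s)
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_borehole(
    geom: BoreholeGeometry,
    flow: AirflowSpec,
    env: Environment,
    inflow: VaporParcel,
    xylem: XylemSource,
    config: SurfaceModelConfig | None = None,
    N: int = 500,
    alphas: FractionationSet | None = None,
) -> SimulationResult:
    """Chain N equal-length segments at steady state along the flow path.

    The outflow (w, R) of segment i-1 is the inflow of segment i. Steady
    inflow conditions are assumed throughout. Raises if the inflow is above
    saturation at stem temperature (condensation is not modeled).
    """
    if N < 1:
        raise ValueError(f"segment count N must be >= 1 (got {N})")
    config = config or SurfaceModelConfig()
    alphas = alphas or FractionationSet.at_temperature(env.T)
    w_sat = saturation_mole_fraction(env.T, env.p)
    if inflow.w > w_sat:
        raise ValueError(
            f"inflow above saturation (w={inflow.w:.4g} > w_sat={w_sat:.4g}):"
            " condensation regime is not modeled"
        )

    seg_length = geom.l / N
    q = flow.carrier_flow()
    g = 2.0 * math.pi * seg_length * vapor_diffusivity(env)

    w = inflow.w
    R = dict(inflow.R)
    segments: list[SegmentState] = []
    evap_vol = 0.0  # volumetric vapor added (m^3/s equivalent)
    for i in range(1, N + 1):
        w_next = (q * w + g * w_sat) / (q + g)
        R = segment_isotope_steady_state(
            config, w, R, w_next, xylem, seg_length, flow, env, alphas
        )
        evap_vol += g * (w_sat - w_next)
        w = w_next
        segments.append(
            SegmentState(position=i * seg_length, w=w, h=w / w_sat, R=dict(R))
        )

    outlet = VaporParcel(w=w, R=dict(R))
    return SimulationResult(
        segments=segments,
        outlet=outlet,
        outlet_h=w / w_sat,
        N=N,
        evaporation_total=evap_vol / molar_volume(env),
        time_constants=isotope_time_constants(
            geom, flow, env, inflow.w, alphas
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """A complete, reusable model configuration (geometry through closure)."""

    geom: BoreholeGeometry
    flow: AirflowSpec
    env: Environment
    inflow: VaporParcel
    xylem: XylemSource
    surface: SurfaceModelConfig = field(default_factory=SurfaceModelConfig)
    N: int = 500
    kinetic_overrides: dict[Species, float] | None = None

    def fractionation(self) -> FractionationSet:
        return FractionationSet.at_temperature(self.env.T, self.kinetic_overrides)

    def run(self) -> SimulationResult:
        return simulate_borehole(
            self.geom,
            self.flow,
            self.env,
            self.inflow,
            self.xylem,
            self.surface,
            self.N,
            self.fractionation(),
        )

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)
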