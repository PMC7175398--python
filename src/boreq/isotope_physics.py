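"""Isotope physics primitives for water vapor in air.

Equilibrium liquid--vapor fractionation (Majoube 1971 polynomials), kinetic
fractionation during molecular diffusion, saturation vapor pressure over
liquid water (Murray 1967), vapor diffusivity in air, ideal-gas molar volume,
and conversions between per-mil delta values and isotope ratios.

Conventions
-----------
* Ratios are normalized to the VSMOW standard, so delta = 0 corresponds to a
  ratio of 1.0. All model equations are homogeneous in the ratio, so the
  absolute VSMOW abundances never enter.
* The equilibrium factor ``alpha_plus`` uses the liquid-over-vapor
  convention: vapor in equilibrium with liquid has R_vapor = R_liquid / alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Species",
    "Environment",
    "FractionationSet",
    "T0",
    "P0",
    "D0",
    "DEFAULT_KINETIC_ALPHA",
    "equilibrium_alpha",
    "kinetic_alpha",
    "saturation_vapor_pressure",
    "vapor_diffusivity",
    "molar_volume",
    "saturation_mole_fraction",
    "delta_to_ratio",
    "ratio_to_delta",
]

#: Standard temperature (K) and pressure (Pa) used for gas-law scalings.
T0 = 273.15
P0 = 101_325.0

#: Diffusivity of water vapor in air at (T0, P0), m^2/s.
D0 = 2.12e-5

#: Molar volume of an ideal gas at (T0, P0), m^3/mol.
V1MOL_STP = 22.414e-3


class Species(str, Enum):
    """Heavy isotopologue of water: H2(18)O or (1)H(2)HO."""

    O18 = "O18"
    H2 = "H2"


# Default kinetic fractionation factors: classical molecular-diffusivity
# ratios of the heavy isotopologues in air (Merlivat-type values).
DEFAULT_KINETIC_ALPHA: dict[Species, float] = {
    Species.O18: 1.0285,
    Species.H2: 1.0251,
}

# Majoube (1971) coefficients for 10^3 ln(alpha+) = a*(10^6/T^2) +
# b*(10^3/T) + c, liquid-vapor equilibrium, T in kelvin.
_MAJOUBE = {
    Species.O18: (1.137, -0.4156, -2.0667),
    Species.H2: (24.844, -76.248, 52.612),
}


@dataclass(frozen=True)
class Environment:
    """Thermodynamic state of the borehole air: temperature (K), pressure (Pa)."""

    T: float
    p: float = P0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive (got {self.T} K)")
        if self.p <= 0:
            raise ValueError(f"pressure must be positive (got {self.p} Pa)")


def equilibrium_alpha(species: Species, T: float) -> float:
    """Equilibrium liquid-vapor fractionation factor alpha+ at temperature T.

    Majoube (1971) polynomial fits; liquid-over-vapor convention, so
    R_vapor = R_liquid / alpha+ and alpha+ > 1 for both species at
    environmental temperatures.

    Parameters
    ----------
    species : Species
    T : float
        Absolute temperature in kelvin. Valid for liquid water; a warning
        is raised outside 230-350 K.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive (got {T} K)")
    if not 230.0 <= T <= 350.0:
        warnings.warn(
            f"equilibrium_alpha evaluated at T={T:.1f} K, outside the "
            "230-350 K range of the Majoube fits",
            stacklevel=2,
        )
    a, b, c = _MAJOUBE[Species(species)]
    ln_alpha_e3 = a * 1.0e6 / T**2 + b * 1.0e3 / T + c
    return math.exp(ln_alpha_e3 / 1000.0)


def kinetic_alpha(species: Species, override: float | None = None) -> float:
    """Kinetic fractionation factor alpha_k (>1 favors the light isotopologue).

    Defaults are the molecular-diffusivity ratios in
    :data:`DEFAULT_KINETIC_ALPHA`; pass ``override`` to use another value
    (``override=1.0`` disables kinetic fractionation).
    """
    if override is not None:
        if override < 1.0:
            raise ValueError(f"kinetic alpha must be >= 1 (got {override})")
        return float(override)
    return DEFAULT_KINETIC_ALPHA[Species(species)]


def saturation_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure over liquid water (Pa), Murray (1967).

    e_sat = 610.78 * exp(17.2693882 * (T - 273.16) / (T - 35.86)),
    anchored at 610.78 Pa at the triple point. Liquid-water branch; below
    ~233 K the formula loses physical meaning.
    """
    if T <= 233.0:
        raise ValueError(
            f"saturation_vapor_pressure requires T > 233 K (got {T} K)"
        )
    return 610.78 * math.exp(17.2693882 * (T - 273.16) / (T - 35.86))


def vapor_diffusivity(env: Environment) -> float:
    """Diffusivity of water vapor in air (m^2/s).

    D = D0 * (p0/p) * (T/T0)^1.88 with D0 = 2.12e-5 m^2/s.
    """
    return D0 * (P0 / env.p) * (env.T / T0) ** 1.88


def molar_volume(env: Environment) -> float:
    """Ideal-gas molar volume (m^3/mol): 22.414 L/mol scaled by T/T0 * p0/p."""
    return V1MOL_STP * (env.T / T0) * (P0 / env.p)


def saturation_mole_fraction(T_stem: float, p: float = P0) -> float:
    """Saturation water-vapor mole fraction w_sat = e_sat(T_stem)/p.

    Raises if e_sat >= p (boiling regime, outside the model's validity).
    """
    esat = saturation_vapor_pressure(T_stem)
    if esat >= p:
        raise ValueError(
            f"e_sat(T)={esat:.0f} Pa >= p={p:.0f} Pa: no vapor-in-air regime"
        )
    return esat / p


def delta_to_ratio(delta: float) -> float:
    """Convert per-mil delta to a VSMOW-normalized ratio (delta=0 -> 1.0)."""
    if delta <= -1000.0:
        raise ValueError(f"delta must exceed -1000 per mil (got {delta})")
    return 1.0 + delta / 1000.0


def ratio_to_delta(ratio: float) -> float:
    """Convert a VSMOW-normalized ratio back to per-mil delta."""
    if ratio <= 0.0:
        raise ValueError(f"ratio must be positive (got {ratio})")
    return (ratio - 1.0) * 1000.0


@dataclass(frozen=True)
class FractionationSet:
    """Equilibrium (alpha+) and kinetic (alpha_k) factors per species at one T."""

    alpha_plus: dict[Species, float]
    alpha_k: dict[Species, float] = field(
        default_factory=lambda: dict(DEFAULT_KINETIC_ALPHA)
    )

    @classmethod
    def at_temperature(
        cls,
        T: float,
        kinetic_overrides: dict[Species, float] | None = None,
    ) -> "FractionationSet":
        """Build the factor set at temperature T (K).

        ``kinetic_overrides`` maps species to alpha_k values replacing the
        diffusivity-ratio defaults (e.g. ``{Species.O18: 1.0}``).
        """
        overrides = kinetic_overrides or {}
        return cls(
            alpha_plus={s: equilibrium_alpha(s, T) for s in Species},
            alpha_k={
                s: kinetic_alpha(s, overrides.get(s)) for s in Species
            },
        )
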