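"""Thermal and kinetic material models for the scald simulation.

Tissue layers are treated with constant (temperature-independent) thermal
properties; the porridge layer uses quadratic polynomials in temperature for
conductivity, density and specific heat, representative of rice-and-milk
products.  Blood perfusion / metabolic heat parameters follow the Pennes
bioheat formulation, and thermal-injury kinetics follow the classical
Henriques–Moritz Arrhenius model.

Units are SI throughout except temperature, which is degrees Celsius at the
module surface (the porridge polynomials are fitted in °C and clinical
temperatures are quoted in °C); the damage kinetics convert to kelvin
internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueLayer",
    "PorridgeModel",
    "PerfusionModel",
    "DamageKinetics",
    "GAS_CONSTANT",
    "porridge_property",
    "thermal_diffusivity",
    "thermal_effusivity",
    "standard_skin_stack",
    "SKIN_LAYER_TABLE",
]

logger = logging.getLogger(__name__)

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class TissueLayer:
    """One homogeneous skin layer with constant thermal properties.

    Parameters
    ----------
    name : str
        Layer label (``"epidermis"``, ``"dermis"``, ...).
    k : float
        Thermal conductivity, W/(m K).
    rho : float
        Density, kg/m^3.
    c : float
        Specific heat, J/(kg K).
    thickness : float
        Layer thickness, m.
    """

    name: str
    k: float
    rho: float
    c: float
    thickness: float

    def __post_init__(self) -> None:
        for attr in ("k", "rho", "c", "thickness"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity k/(rho*c), m^2/s."""
        return thermal_diffusivity(self.k, self.rho, self.c)

    @property
    def effusivity(self) -> float:
        """Thermal effusivity sqrt(k*rho*c), W s^1/2/(m^2 K)."""
        return thermal_effusivity(self.k, self.rho, self.c)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "k": self.k,
            "rho": self.rho,
            "c": self.c,
            "thickness": self.thickness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueLayer":
        return cls(**{k: d[k] for k in ("name", "k", "rho", "c", "thickness")})


# Handbook-style properties of the four skin layers used throughout:
# k (W/m K), rho (kg/m3), c (J/kg K), thickness (m).  Epidermis thickness is
# the adult-forearm default and is overridden per scenario.
SKIN_LAYER_TABLE: tuple[TissueLayer, ...] = (
    TissueLayer("epidermis", 0.22, 1200.0, 3600.0, 60e-6),
    TissueLayer("dermis", 0.40, 1200.0, 3600.0, 2e-3),
    TissueLayer("subcutaneous", 0.20, 1000.0, 2500.0, 10e-3),
    TissueLayer("muscle", 0.45, 1000.0, 3800.0, 30e-3),
)

# Quadratic fits (coefficients ordered [T^2, T, 1], T in °C) for hot
# rice-and-milk porridge from food-processing property data.
PORRIDGE_K_COEFFS = (-6.0e-6, 0.0015, 0.5061)  # W/(m K)
PORRIDGE_RHO_COEFFS = (-3.4e-3, 0.0377, 1046.6)  # kg/m^3
PORRIDGE_C_COEFFS = (-4.0e-3, 0.2000, 3743.5)  # J/(kg K)

#: Temperature range (°C) over which the porridge fits are considered valid.
PORRIDGE_VALID_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class PorridgeModel:
    """Temperature-dependent porridge layer.

    ``k_coeffs``, ``rho_coeffs`` and ``c_coeffs`` are quadratic polynomial
    coefficients ordered ``[T^2, T^1, T^0]`` with T in °C; properties come out
    in SI units.  ``temperature`` is the uniform initial spill temperature and
    ``thickness`` the spill layer thickness.
    """

    temperature: float = 70.0  # °C
    thickness: float = 3e-3  # m
    k_coeffs: tuple[float, float, float] = PORRIDGE_K_COEFFS
    rho_coeffs: tuple[float, float, float] = PORRIDGE_RHO_COEFFS
    c_coeffs: tuple[float, float, float] = PORRIDGE_C_COEFFS

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("porridge thickness must be positive")

    def conductivity(self, T):
        return porridge_property(self, "conductivity", T)

    def density(self, T):
        return porridge_property(self, "density", T)

    def specific_heat(self, T):
        return porridge_property(self, "specific_heat", T)

    def diffusivity(self, T: float) -> float:
        return thermal_diffusivity(
            self.conductivity(T), self.density(T), self.specific_heat(T)
        )

    def effusivity(self, T: float) -> float:
        return thermal_effusivity(
            self.conductivity(T), self.density(T), self.specific_heat(T)
        )

    def with_conditions(self, temperature: float, thickness: float) -> "PorridgeModel":
        return replace(self, temperature=temperature, thickness=thickness)


_PROPERTY_COEFFS = {
    "conductivity": "k_coeffs",
    "density": "rho_coeffs",
    "specific_heat": "c_coeffs",
}


def porridge_property(model: PorridgeModel, which: str, T):
    """Evaluate one porridge property polynomial at temperature ``T`` (°C).

    ``which`` is one of ``"conductivity"``, ``"density"``, ``"specific_heat"``.
    Accepts scalars or numpy arrays.  Temperatures outside the fit's validity
    range are allowed but logged as a warning: the quadratics extrapolate
    smoothly, but the fit was made on liquid porridge between freezing and
    boiling.
    """
    try:
        coeffs = getattr(model, _PROPERTY_COEFFS[which])
    except KeyError:
        raise ValueError(
            f"unknown property {which!r}; expected one of {sorted(_PROPERTY_COEFFS)}"
        ) from None
    lo, hi = PORRIDGE_VALID_RANGE
    t = np.asarray(T, dtype=float)
    if np.any(t < lo) or np.any(t > hi):
        logger.warning(
            "porridge %s evaluated outside validity range [%g, %g] °C", which, lo, hi
        )
    a, b, c = coeffs
    out = (a * t + b) * t + c
    return float(out) if np.isscalar(T) else out


def thermal_diffusivity(k: float, rho: float, c: float) -> float:
    """Thermal diffusivity a = k/(rho*c) in m^2/s."""
    if k <= 0 or rho <= 0 or c <= 0:
        raise ValueError("thermal properties must be positive")
    return k / (rho * c)


def thermal_effusivity(k: float, rho: float, c: float) -> float:
    """Thermal effusivity e = sqrt(k*rho*c) in W s^1/2/(m^2 K).

    Governs the interface temperature when two semi-infinite bodies are
    brought into sudden contact: T_c = (e1*T1 + e2*T2)/(e1 + e2).
    """
    if k <= 0 or rho <= 0 or c <= 0:
        raise ValueError("thermal properties must be positive")
    return math.sqrt(k * rho * c)


def standard_skin_stack(epidermis_thickness: float = 60e-6) -> list[TissueLayer]:
    """Return the four-layer forearm skin stack with a given epidermis depth.

    The deeper layers (dermis 2 mm, subcutaneous 10 mm, muscle 30 mm) keep
    their default thicknesses; only the epidermis is varied, which is how
    inter-individual skin-thickness differences (children vs adults) are
    represented.
    """
    if epidermis_thickness <= 0:
        raise ValueError("epidermis thickness must be positive")
    epi = replace(SKIN_LAYER_TABLE[0], thickness=epidermis_thickness)
    return [epi, *SKIN_LAYER_TABLE[1:]]


@dataclass(frozen=True)
class PerfusionModel:
    """Blood perfusion and metabolic heat source terms of the Pennes equation.

    The volumetric source is ``W_b * rho_b * c_b * (T_b - T) + Q_met`` in
    perfused tissue.  The epidermis is avascular, so perfusion and metabolic
    production are applied from the dermis down; the porridge never carries
    these terms.

    Defaults are physiologic textbook values: blood density 1060 kg/m^3,
    blood specific heat 3770 J/(kg K), arterial temperature 37 °C, dermal
    perfusion rate 1.25e-3 1/s and metabolic production 400 W/m^3.  For
    exposures up to about a minute these terms perturb the damage integral
    only at the few-percent level.
    """

    w_b: float = 1.25e-3  # 1/s, volumetric perfusion rate in perfused layers
    rho_b: float = 1060.0  # kg/m^3
    c_b: float = 3770.0  # J/(kg K)
    t_b: float = 37.0  # °C
    q_met: float = 400.0  # W/m^3 in perfused layers
    perfused_layers: tuple[str, ...] = ("dermis", "subcutaneous", "muscle")

    @property
    def volumetric_coefficient(self) -> float:
        """W_b * rho_b * c_b, W/(m^3 K)."""
        return self.w_b * self.rho_b * self.c_b

    def source(self, T, perfused=True):
        """Volumetric Pennes source at temperature ``T`` (°C), W/m^3."""
        if not perfused:
            return np.zeros_like(np.asarray(T, dtype=float)) if not np.isscalar(T) else 0.0
        return self.volumetric_coefficient * (self.t_b - np.asarray(T, dtype=float)) + self.q_met


@dataclass(frozen=True)
class DamageKinetics:
    """Arrhenius kinetics of thermal cell damage (Henriques–Moritz).

    The damage rate is ``P * exp(-dE/(R*T_K))`` for basal temperatures above
    the injury threshold and zero below it.  The classical frequency factor
    P = 3.1e98 1/s pairs with an activation energy of 6.28e5 J/mol; the
    injury threshold for hot liquids is 43.0 °C.
    """

    p: float = 3.1e98  # 1/s
    de: float = 6.28e5  # J/mol
    r: float = GAS_CONSTANT  # J/(mol K)
    t_threshold: float = 43.0  # °C

    def __post_init__(self) -> None:
        if self.p <= 0 or self.de <= 0 or self.r <= 0:
            raise ValueError("kinetic constants must be positive")
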