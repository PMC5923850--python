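"""Henriques damage integral and burn-severity classification.

The damage index Omega = -ln(C_tau/C_0) measures the surviving fraction of
basal-layer cells after a heat exposure.  Its rate follows first-order
Arrhenius kinetics, integrated over the time the basal-layer temperature
exceeds the injury threshold (43.0 °C for hot liquids).  Omega = 0.53 marks
the limit for superficial burns and Omega = 1.0 the limit for superficial
partial-thickness burns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import DamageKinetics

__all__ = [
    "DamageResult",
    "BurnClass",
    "damage_rate",
    "accumulate",
    "classify",
    "SUPERFICIAL_LIMIT",
    "SUPERFICIAL_PARTIAL_LIMIT",
]

SUPERFICIAL_LIMIT = 0.53
SUPERFICIAL_PARTIAL_LIMIT = 1.0

# Burn classes in increasing severity.  Depth-resolved deep-partial /
# full-thickness grading would require per-depth damage profiles and is not
# attempted: classification is from the basal-layer integral alone.
BurnClass = str
CLASS_NONE = "none"
CLASS_SUPERFICIAL = "superficial"
CLASS_SUPERFICIAL_PARTIAL = "superficial partial-thickness"


@dataclass(frozen=True)
class DamageResult:
    """Accumulated basal-layer damage and its classification."""

    omega: float
    omega_series: np.ndarray
    times: np.ndarray

    @property
    def burn_class(self) -> BurnClass:
        return classify(self.omega)


def damage_rate(kinetics: DamageKinetics, T):
    """Damage accrual rate dOmega/dt at basal temperature ``T`` (°C), 1/s.

    Zero at and below the injury threshold; above it the Arrhenius rate
    P*exp(-dE/(R*T_K)) with T_K in kelvin.  Accepts scalars or arrays.
    """
    t = np.asarray(T, dtype=float)
    rate = np.where(
        t > kinetics.t_threshold,
        kinetics.p * np.exp(-kinetics.de / (kinetics.r * (t + 273.15))),
        0.0,
    )
    return float(rate) if np.isscalar(T) else rate


def accumulate(
    kinetics: DamageKinetics, basal_temperatures, dt: float, omega0: float = 0.0
) -> DamageResult:
    """Integrate the damage rate over a uniformly sampled temperature series.

    Uses the rectangle rule at spacing ``dt``: with the sub-millisecond steps
    the solver takes, the quadrature error is far below the uncertainty of
    the kinetic constants.  ``omega0`` seeds the integral so that series may
    be accumulated piecewise (damage is additive over concatenated phases).
    """
    t_series = np.asarray(basal_temperatures, dtype=float)
    if t_series.size == 0:
        return DamageResult(omega=omega0, omega_series=np.array([]), times=np.array([]))
    rates = damage_rate(kinetics, t_series)
    omega_series = omega0 + np.cumsum(rates) * dt
    times = (np.arange(t_series.size) + 1) * dt
    return DamageResult(
        omega=float(omega_series[-1]), omega_series=omega_series, times=times
    )


def classify(omega: float) -> BurnClass:
    """Map a basal-layer damage integral to a burn-severity class.

    Below 0.53 the injury does not reach the superficial-burn limit; from
    0.53 (inclusive) it is a superficial burn, and from 1.0 (inclusive) at
    least a superficial partial-thickness burn.
    """
    if omega < 0:
        raise ValueError("damage integral cannot be negative")
    if omega < SUPERFICIAL_LIMIT:
        return CLASS_NONE
    if omega < SUPERFICIAL_PARTIAL_LIMIT:
        return CLASS_SUPERFICIAL
    return CLASS_SUPERFICIAL_PARTIAL
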