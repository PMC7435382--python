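"""Ideal-orifice pressure/flow model of a mask chamber.

A mask with a single vent of cross-section S behaves, in the frictionless
ideal-fluid limit, like a chamber whose outflow speed u satisfies
Bernoulli's relation ΔP = ½ρu², so the volumetric flow through the vent is

    F = sign(ΔP) · S · sqrt(2|ΔP| / ρ),      ΔP = P_chamber − P_atmos.

With the standard sea-level constants (ρ = 1.225 kg/m³, P_atmos = 101,325 Pa)
and the reference spirometer's 2.826×10⁻³ m² sensing surface, the published
closed form rounds the litres-per-second coefficient to 2.9:

    F [L/s] = ±2.9 · sqrt(|P − 101,325|).

Note the printed 2.9 is *not* what the stated S and ρ re-derive to
(S·sqrt(2/ρ)·1000 ≈ 3.611); both values are kept verbatim — the closed form
is an illustrative model, and real masks deviate from it anyway, which is
why calibration is regression-based.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ATMOSPHERIC_PRESSURE_PA",
    "AIR_DENSITY_KG_M3",
    "ORIFICE_AREA_M2",
    "STANDARD_COEFFICIENT_LPS",
    "OrificeEnvironment",
    "ideal_flow_from_pressure",
    "ideal_pressure_from_flow",
    "standard_flow_lps",
]

ATMOSPHERIC_PRESSURE_PA = 101_325.0
AIR_DENSITY_KG_M3 = 1.225
ORIFICE_AREA_M2 = 2.826e-3
#: Printed L/s-per-sqrt(Pa) coefficient of the standard-condition closed form.
STANDARD_COEFFICIENT_LPS = 2.9


@dataclass(frozen=True)
class OrificeEnvironment:
    """Ambient conditions and vent geometry for the ideal model.

    All three fields must be strictly positive.
    """

    atmospheric_pressure: float = ATMOSPHERIC_PRESSURE_PA  # Pa
    air_density: float = AIR_DENSITY_KG_M3  # kg/m^3
    orifice_area: float = ORIFICE_AREA_M2  # m^2

    def __post_init__(self) -> None:
        for name in ("atmospheric_pressure", "air_density", "orifice_area"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"OrificeEnvironment.{name} must be finite and > 0, got {v}")


def _check_finite(x: np.ndarray | float, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} must be finite")
    return arr


def ideal_flow_from_pressure(
    chamber_pressure: np.ndarray | float,
    env: OrificeEnvironment = OrificeEnvironment(),
) -> np.ndarray | float:
    """Volumetric flow (m³/s, positive = outflow) through the vent.

    Odd in ΔP = chamber_pressure − atmospheric and monotone nondecreasing
    in chamber pressure.
    """
    p = _check_finite(chamber_pressure, "chamber_pressure")
    dp = p - env.atmospheric_pressure
    flow = np.sign(dp) * env.orifice_area * np.sqrt(2.0 * np.abs(dp) / env.air_density)
    return flow if np.ndim(chamber_pressure) else float(flow)


def ideal_pressure_from_flow(
    flow: np.ndarray | float,
    env: OrificeEnvironment = OrificeEnvironment(),
) -> np.ndarray | float:
    """Chamber pressure (Pa) sustaining a signed flow; exact inverse of
    :func:`ideal_flow_from_pressure`."""
    f = _check_finite(flow, "flow")
    dp = np.sign(f) * env.air_density * (f / env.orifice_area) ** 2 / 2.0
    p = env.atmospheric_pressure + dp
    return p if np.ndim(flow) else float(p)


def standard_flow_lps(
    chamber_pressure: np.ndarray | float,
    coefficient: float = STANDARD_COEFFICIENT_LPS,
) -> np.ndarray | float:
    """Standard-condition closed form: F = ±coefficient·sqrt(|P − 101,325|) L/s.

    The branch point P = 101,325 Pa, undefined in the published piecewise
    form, returns 0 by continuity.
    """
    p = _check_finite(chamber_pressure, "chamber_pressure")
    dp = p - ATMOSPHERIC_PRESSURE_PA
    flow = np.sign(dp) * coefficient * np.sqrt(np.abs(dp))
    return flow if np.ndim(chamber_pressure) else float(flow)
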