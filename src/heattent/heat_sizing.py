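"""Heating-requirement physics and unit conversions for sizing a heat tent.

This module works in the imperial units that greenhouse heater sizing is
quoted in (ft², h·ft²·°F/BTU, BTU/h); everything downstream of sizing works
in SI/°C, and the conversions live here.

The core relation is the steady conduction load

    Q = ΔT · A / R

where Q is the heating rate (BTU/h) needed to hold a temperature
differential ΔT (°F) across a covering of surface area A (ft²) and thermal
resistance R (h·ft²·°F/BTU).  A tent that is not airtight additionally
loses heat to air infiltration; the difference between the installed
heater capacity and the conductive load is the budget available to cover
that infiltration loss, and dividing the stored heat of one tent volume of
air by that budget gives the implied air-exchange interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError, DomainError

__all__ = [
    "TentSpec",
    "BTU_PER_HOUR_TO_WATTS",
    "AIR_HEAT_CAPACITY_BTU_FT3_F",
    "required_heat",
    "btu_per_hour_to_watts",
    "watts_to_btu_per_hour",
    "celsius_delta_to_fahrenheit_delta",
    "fahrenheit_delta_to_celsius_delta",
    "infiltration_budget",
    "air_exchange_interval",
    "printed",
]

#: Conversion used for all heater ratings: 1 BTU/h = 0.293 W.
BTU_PER_HOUR_TO_WATTS = 0.293

#: Volumetric heat capacity of air near 20 °C, BTU/(ft³·°F).
AIR_HEAT_CAPACITY_BTU_FT3_F = 0.018


def _default_propane() -> dict[str, float]:
    return {"low": 10_000.0, "medium": 12_000.0, "high": 15_000.0}


@dataclass
class TentSpec:
    """Physical constants of one heat tent.

    Parameters
    ----------
    surface_area : float
        Covering surface area, ft².
    r_value : float
        Thermal resistance of the covering, h·ft²·°F/BTU.
    volume : float
        Interior air volume, ft³.  The default approximates a 7.2 m ×
        5.4 m gothic tent of ~3 m apex height.
    electric_heater_output : float
        Rated output of the electric heater, BTU/h.
    propane_output_by_setting : dict
        Output of the propane tank-top heater at each setting, BTU/h.
    fan_power : float
        Circulation fan draw, W (not a heat input in the sizing math).
    """

    surface_area: float = 1100.0
    r_value: float = 0.87
    volume: float = 3400.0
    electric_heater_output: float = 17_065.0
    propane_output_by_setting: dict[str, float] = field(default_factory=_default_propane)
    fan_power: float = 75.0

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise ConfigError(f"surface_area must be positive, got {self.surface_area}")
        if self.r_value <= 0:
            raise ConfigError(f"r_value must be positive, got {self.r_value}")
        if self.volume <= 0:
            raise ConfigError(f"volume must be positive, got {self.volume}")
        p = self.propane_output_by_setting
        settings = ("low", "medium", "high")
        if set(p) != set(settings):
            raise ConfigError(f"propane settings must be {settings}, got {sorted(p)}")
        if not (p["low"] < p["medium"] < p["high"]):
            raise ConfigError("propane outputs must be ordered low < medium < high")

    @property
    def u_value(self) -> float:
        """Heat-loss coefficient U = 1/R, BTU/(h·ft²·°F)."""
        return 1.0 / self.r_value

    @property
    def conductive_ua(self) -> float:
        """Whole-tent conductive loss coefficient A/R, BTU/(h·°F)."""
        return self.surface_area / self.r_value

    def total_heat_input(self, propane_setting: str = "medium") -> float:
        """Electric plus propane output at the given setting, BTU/h."""
        if propane_setting == "off":
            return self.electric_heater_output
        try:
            propane = self.propane_output_by_setting[propane_setting]
        except KeyError as exc:
            raise ConfigError(f"unknown propane setting {propane_setting!r}") from exc
        return self.electric_heater_output + propane


def required_heat(spec: TentSpec, delta_t: float) -> float:
    """Conductive heating load Q = ΔT·A/R in BTU/h for a differential in °F."""
    if delta_t < 0:
        raise DomainError(f"delta_t must be non-negative, got {delta_t}")
    return delta_t * spec.surface_area / spec.r_value


def btu_per_hour_to_watts(q: float) -> float:
    """Convert a heating rate from BTU/h to W (1 BTU/h = 0.293 W)."""
    if q < 0:
        raise DomainError(f"heating rate must be non-negative, got {q}")
    return q * BTU_PER_HOUR_TO_WATTS


def watts_to_btu_per_hour(w: float) -> float:
    """Inverse of :func:`btu_per_hour_to_watts`."""
    if w < 0:
        raise DomainError(f"power must be non-negative, got {w}")
    return w / BTU_PER_HOUR_TO_WATTS


def celsius_delta_to_fahrenheit_delta(dc: float) -> float:
    """Convert a temperature *differential* from °C to °F (×1.8, no offset)."""
    return dc * 1.8


def fahrenheit_delta_to_celsius_delta(df: float) -> float:
    """Convert a temperature *differential* from °F to °C (÷1.8, no offset)."""
    return df / 1.8


def infiltration_budget(spec: TentSpec, total_input: float, delta_t: float) -> float:
    """Heater capacity left over after conduction, attributed to infiltration.

    ``total_input − required_heat(spec, delta_t)`` in BTU/h; raises if the
    installed capacity cannot even cover the conductive load.
    """
    conductive = required_heat(spec, delta_t)
    if total_input < conductive:
        raise DomainError(
            f"total input {total_input} BTU/h is below the conductive "
            f"requirement {conductive:.1f} BTU/h"
        )
    return total_input - conductive


def air_exchange_interval(
    spec: TentSpec,
    infiltration_loss: float,
    delta_t: float,
    air_heat_capacity: float = AIR_HEAT_CAPACITY_BTU_FT3_F,
) -> float:
    """Minutes per complete air exchange implied by an infiltration loss.

    One tent volume of air warmed by ``delta_t`` stores
    ``volume · c · delta_t`` BTU; an infiltration loss rate of
    ``infiltration_loss`` BTU/h therefore flushes the volume
    ``loss / stored`` times per hour.
    """
    if infiltration_loss <= 0 or delta_t <= 0 or air_heat_capacity <= 0:
        raise DomainError("infiltration_loss, delta_t and air_heat_capacity must be > 0")
    exchanges_per_hour = infiltration_loss / (spec.volume * air_heat_capacity * delta_t)
    return 60.0 / exchanges_per_hour


def printed(x: float) -> int:
    """Round to integer, half away from zero, as sizing results are printed."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))
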