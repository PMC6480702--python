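"""Lumped heat-balance model of one heat tent.

A single thermal node (interior air plus canopy and near-surface soil)
exchanges heat with ambient through two parallel paths — conduction
through the covering and air infiltration — and receives heat from the
electric and propane heaters (and optionally a daytime solar gain):

    C dT_in/dt = Q_heaters + Q_solar − (UA_cond + UA_inf) (T_in − T_out)

UA coefficients are carried in the sizing units BTU/(h·°F) and converted
to W/°C internally; the state integrates with explicit Euler at a step
small against the thermal time constant.  Opening the vents (day mode)
switches infiltration to a much larger coefficient so the interior tracks
ambient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta

from .errors import ConfigError, DomainError
from .heat_sizing import (
    BTU_PER_HOUR_TO_WATTS,
    TentSpec,
    fahrenheit_delta_to_celsius_delta,
    required_heat,
)

__all__ = [
    "ThermalParams",
    "ThermalState",
    "UA_BTU_F_TO_W_C",
    "step",
    "steady_state_differential",
    "calibrate_infiltration",
    "time_constant_s",
]

#: BTU/(h·°F) → W/°C: 0.293 W per BTU/h times 1.8 °F per °C.
UA_BTU_F_TO_W_C = BTU_PER_HOUR_TO_WATTS * 1.8

PROPANE_SETTINGS = ("off", "low", "medium", "high")


@dataclass
class ThermalParams:
    """Loss coefficients and lumped heat capacity of the tent interior.

    ``conductive_ua`` and the infiltration coefficients are in
    BTU/(h·°F); ``heat_capacity`` is kJ/°C for the lumped node (air alone
    is ~112 kJ/°C for ~93 m³; the default multiplies that up for canopy
    and soil mass).  ``solar_gain_peak`` (W) adds a daylight half-sine
    gain and is off by default for night-only experiments.
    """

    conductive_ua: float = 1100.0 / 0.87
    infiltration_ua_closed: float = 2772.4
    infiltration_ua_open: float = 50_000.0
    heat_capacity: float = 500.0
    solar_gain_peak: float = 0.0
    dawn_hour: float = 6.0
    dusk_hour: float = 20.0

    def __post_init__(self) -> None:
        for name in ("conductive_ua", "infiltration_ua_closed", "infiltration_ua_open",
                     "heat_capacity", "solar_gain_peak"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.infiltration_ua_open <= self.infiltration_ua_closed:
            raise ConfigError("infiltration_ua_open must exceed infiltration_ua_closed")

    def total_ua(self, vent_open: bool) -> float:
        """Loss coefficient for the current vent state, BTU/(h·°F)."""
        inf = self.infiltration_ua_open if vent_open else self.infiltration_ua_closed
        return self.conductive_ua + inf


@dataclass(frozen=True)
class ThermalState:
    """Instantaneous state of the tent interior."""

    interior_temp: float
    time: datetime
    vent_open: bool = False
    electric_heater_on: bool = False
    propane_setting: str = "off"

    def __post_init__(self) -> None:
        if not math.isfinite(self.interior_temp):
            raise DomainError("interior_temp must be finite")
        if self.propane_setting not in PROPANE_SETTINGS:
            raise ConfigError(f"propane_setting must be one of {PROPANE_SETTINGS}")


def _heater_power_w(state: ThermalState, spec: TentSpec) -> float:
    q_btu = 0.0
    if state.electric_heater_on:
        q_btu += spec.electric_heater_output
    if state.propane_setting != "off":
        q_btu += spec.propane_output_by_setting[state.propane_setting]
    return q_btu * BTU_PER_HOUR_TO_WATTS


def _solar_gain_w(params: ThermalParams, when: datetime) -> float:
    if params.solar_gain_peak <= 0:
        return 0.0
    h = when.hour + when.minute / 60.0 + when.second / 3600.0
    if not (params.dawn_hour <= h < params.dusk_hour):
        return 0.0
    frac = (h - params.dawn_hour) / (params.dusk_hour - params.dawn_hour)
    return params.solar_gain_peak * math.sin(math.pi * frac)


def step(
    state: ThermalState,
    ambient_temp: float,
    params: ThermalParams,
    spec: TentSpec,
    dt: float,
) -> ThermalState:
    """Advance the interior temperature by one explicit-Euler step of ``dt`` s."""
    if not 0 < dt <= 60:
        raise DomainError(f"dt must be in (0, 60] s, got {dt}")
    if not (math.isfinite(ambient_temp) and math.isfinite(state.interior_temp)):
        raise DomainError("non-finite temperature input")

    ua_w_per_c = params.total_ua(state.vent_open) * UA_BTU_F_TO_W_C
    q_in = _heater_power_w(state, spec) + _solar_gain_w(params, state.time)
    net_w = q_in - ua_w_per_c * (state.interior_temp - ambient_temp)
    d_temp = net_w * dt / (params.heat_capacity * 1000.0)
    return replace(
        state,
        interior_temp=state.interior_temp + d_temp,
        time=state.time + timedelta(seconds=dt),
    )


def steady_state_differential(params: ThermalParams, q_total: float) -> float:
    """Equilibrium interior−exterior differential (°C) under constant heating.

    With vents closed, Q/(UA_cond + UA_inf_closed) gives the differential
    in °F; returned converted to °C.
    """
    ua = params.total_ua(vent_open=False)
    if ua <= 0:
        raise DomainError("total UA must be positive")
    return fahrenheit_delta_to_celsius_delta(q_total / ua)


def calibrate_infiltration(spec: TentSpec, target_delta: float, q_total: float) -> float:
    """Infiltration coefficient that makes ``q_total`` hold ``target_delta``.

    Solves Q/(UA_cond + UA_inf) = ΔT for UA_inf, with ``target_delta`` in
    °C and the result in BTU/(h·°F).  Raises if ``q_total`` cannot even
    cover the conductive load at the target differential.
    """
    if target_delta <= 0:
        raise DomainError(f"target_delta must be positive, got {target_delta}")
    delta_f = target_delta * 1.8
    if q_total < required_heat(spec, delta_f):
        raise DomainError(
            f"q_total {q_total} BTU/h cannot cover the conductive load at "
            f"{target_delta} °C"
        )
    return q_total / delta_f - spec.conductive_ua


def time_constant_s(params: ThermalParams, vent_open: bool = False) -> float:
    """Thermal time constant C/UA in seconds for the given vent state."""
    ua_w_per_c = params.total_ua(vent_open) * UA_BTU_F_TO_W_C
    if ua_w_per_c <= 0:
        raise DomainError("total UA must be positive")
    return params.heat_capacity * 1000.0 / ua_w_per_c
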