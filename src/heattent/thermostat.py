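"""Differential thermostat control loop and its log-file dialect.

Re-implements the Raspberry-Pi controller that held heat tents a fixed
number of degrees above ambient at night: two temperature sensors
(interior, exterior) are polled, the interior−exterior differential is
compared against the setpoint, and the electric heater is switched fully
on when the differential is strictly below the setpoint and fully off
when strictly above it (bang-bang control; at exactly the setpoint the
previous command is retained).  An invalid sensor reading raises the
SENSOR condition: the heater command is frozen until a valid reading
arrives.

The log dialect is plain CSV without a header —
``timestamp,indoor,outdoor,status`` — and a blank line is appended before
each new logging session, exactly as the field device wrote its files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, LogParseError, SimulationError
from .heat_sizing import TentSpec
from .schedule import NightWindow
from .tent_thermal import ThermalParams, ThermalState, step as thermal_step
from .weather_synth import WeatherSeries

__all__ = [
    "ControlConfig",
    "LogRecord",
    "SensorSpec",
    "SensorFault",
    "SENSOR_FAULT",
    "decide",
    "read_sensor",
    "run_controller",
    "ControllerRun",
    "write_log",
    "read_log",
]

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"


@dataclass
class ControlConfig:
    """Thermostat setpoint and timing.

    ``setpoint_differential`` is the target interior−exterior differential
    in °C.  ``poll_sleep`` is the pause between control-loop iterations
    (the field device slept half a second).  ``hysteresis_band`` widens
    the dead zone symmetrically around the setpoint; the field script ran
    with zero hysteresis.
    """

    setpoint_differential: float = 4.0
    poll_sleep: float = 0.5
    log_interval: float = 60.0
    hysteresis_band: float = 0.0

    def __post_init__(self) -> None:
        if self.setpoint_differential <= 0:
            raise ConfigError("setpoint_differential must be positive")
        if self.poll_sleep <= 0 or self.log_interval <= 0:
            raise ConfigError("poll_sleep and log_interval must be positive")
        if self.hysteresis_band < 0:
            raise ConfigError("hysteresis_band must be non-negative")


@dataclass(frozen=True)
class LogRecord:
    """One controller log row: time, indoor/outdoor °C, heater status."""

    timestamp: datetime
    indoor_temp: float
    outdoor_temp: float
    heater_status: str  # "ON" | "OFF"

    def __post_init__(self) -> None:
        if self.heater_status not in ("ON", "OFF"):
            raise ConfigError(f"heater_status must be ON/OFF, got {self.heater_status!r}")
        if not (math.isfinite(self.indoor_temp) and math.isfinite(self.outdoor_temp)):
            raise DomainError("log temperatures must be finite")


@dataclass
class SensorSpec:
    """Error model of a temperature sensor.

    ``accuracy`` bounds a uniform read error (datasheet ± bound),
    ``resolution`` is the quantization step of reported values, and
    ``failure_rate`` is the per-read probability of an invalid reading.
    Defaults model the Pi's DS18B20 probes (±0.5 °C, 1/16 °C steps); the
    HOBO loggers are ±0.2 °C at a 15-min cadence.
    """

    accuracy: float = 0.5
    resolution: float = 0.0625
    sampling_interval: float = 1.0
    failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.accuracy < 0 or self.resolution < 0:
            raise ConfigError("accuracy and resolution must be non-negative")
        if not 0 <= self.failure_rate < 1:
            raise ConfigError("failure_rate must be in [0, 1)")


class SensorFault:
    """Sentinel returned by :func:`read_sensor` for an invalid reading."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SENSOR"


SENSOR_FAULT = SensorFault()


def decide(indoor: float, outdoor: float, config: ControlConfig, current_on: bool) -> bool:
    """Bang-bang heater command from the interior−exterior differential.

    ON strictly below ``setpoint − h/2``, OFF strictly above
    ``setpoint + h/2``, previous command retained inside the band (and at
    exactly the setpoint when the band is zero).
    """
    if not (math.isfinite(indoor) and math.isfinite(outdoor)):
        raise DomainError("decide requires finite temperatures")
    differential = indoor - outdoor
    half = config.hysteresis_band / 2.0
    if differential < config.setpoint_differential - half:
        return True
    if differential > config.setpoint_differential + half:
        return False
    return current_on


def read_sensor(
    true_temp: float, spec: SensorSpec, rng: np.random.Generator
) -> Union[float, SensorFault]:
    """Measure a true temperature through the sensor error model.

    Returns ``true_temp`` plus a uniform error in [−accuracy, +accuracy],
    quantized to the sensor resolution — or :data:`SENSOR_FAULT` with
    probability ``failure_rate``.
    """
    if spec.failure_rate > 0 and rng.random() < spec.failure_rate:
        return SENSOR_FAULT
    measured = true_temp
    if spec.accuracy > 0:
        measured += rng.uniform(-spec.accuracy, spec.accuracy)
    if spec.resolution > 0:
        measured = round(measured / spec.resolution) * spec.resolution
    return measured


@dataclass
class ControllerRun:
    """Outputs of a closed-loop simulation.

    ``sessions`` holds one list of log records per night; ``trace`` is the
    per-poll state (true temperatures, measured temperatures, heater and
    vent state, fault flag).
    """

    sessions: list[list[LogRecord]]
    trace: pd.DataFrame
    fault_count: int = 0

    def night_duty_cycle(self) -> float:
        """Fraction of night polls with the electric heater commanded on."""
        night = self.trace[self.trace["night"]]
        if night.empty:
            return float("nan")
        return float(night["heater_on"].mean())

    def mean_night_differential(self, per_night: bool = False):
        """Mean true interior−exterior differential over night polls.

        With ``per_night=True`` returns one mean per session date instead
        of the pooled mean over all night samples.
        """
        night = self.trace[self.trace["night"]].copy()
        if night.empty:
            return float("nan")
        diff = night["interior_temp"] - night["ambient_temp"]
        if not per_night:
            return float(diff.mean())
        # Group by "night id": a night that wraps midnight belongs to the
        # evening it started on.
        ts = pd.to_datetime(night["time"])
        night_id = (ts - pd.Timedelta(hours=12)).dt.date
        return diff.groupby(night_id).mean()


def run_controller(
    weather: WeatherSeries,
    spec: TentSpec,
    params: ThermalParams,
    config: ControlConfig,
    interior_sensor: SensorSpec,
    exterior_sensor: SensorSpec,
    night: NightWindow = NightWindow(),
    seed: int = 0,
    propane_setting: str = "medium",
    poll_interval: float = 2.0,
    day_step: float = 10.0,
) -> ControllerRun:
    """Simulate the thermostat closed-loop over a weather series.

    During the night window the tent is sealed (vent closed), the propane
    heater runs at ``propane_setting``, both sensors are polled every
    ``poll_interval`` seconds, and the electric heater follows
    :func:`decide`; a log record is emitted whenever ``log_interval``
    elapses within a session (one session per night).  Outside the window
    all heaters are off, the vents are open and the interior simply
    relaxes toward ambient at the coarser ``day_step``.
    """
    frame = weather.frame
    if len(frame) < 2:
        raise SimulationError("weather series too short to simulate")
    t_epoch = frame.index.view("int64") / 1e9
    temps = frame["temp_c"].to_numpy()

    rng_interior = np.random.default_rng([seed, 1])
    rng_exterior = np.random.default_rng([seed, 2])

    t0 = frame.index[0].to_pydatetime()
    t_end = frame.index[-1].to_pydatetime()

    state = ThermalState(
        interior_temp=float(temps[0]),
        time=t0,
        vent_open=not night.contains(t0),
        electric_heater_on=False,
        propane_setting="off",
    )

    sessions: list[list[LogRecord]] = []
    current_session: list[LogRecord] | None = None
    session_elapsed = 0.0
    fault_count = 0
    heater_cmd = False
    last_indoor: float | None = None
    last_outdoor: float | None = None

    rows: list[tuple] = []

    was_night = night.contains(t0)
    if was_night:
        current_session = []
        sessions.append(current_session)
        state = ThermalState(state.interior_temp, state.time, False, False, propane_setting)

    while state.time < t_end:
        is_night = night.contains(state.time)

        if is_night and not was_night:
            # Seal the tent and start a new logging session.
            current_session = []
            sessions.append(current_session)
            session_elapsed = 0.0
            heater_cmd = False
            state = ThermalState(state.interior_temp, state.time, False, False, propane_setting)
        elif was_night and not is_night:
            # Open up for the day; controller is powered down.
            current_session = None
            heater_cmd = False
            state = ThermalState(state.interior_temp, state.time, True, False, "off")
        was_night = is_night

        now = state.time.timestamp()
        ambient = float(np.interp(now, t_epoch, temps))

        fault = False
        if is_night:
            indoor = read_sensor(state.interior_temp, interior_sensor, rng_interior)
            outdoor = read_sensor(ambient, exterior_sensor, rng_exterior)
            if isinstance(indoor, SensorFault) or isinstance(outdoor, SensorFault):
                fault = True
                fault_count += 1
            else:
                last_indoor, last_outdoor = indoor, outdoor
                heater_cmd = decide(indoor, outdoor, config, heater_cmd)
            state = ThermalState(state.interior_temp, state.time, False, heater_cmd,
                                 propane_setting)
        dt = poll_interval if is_night else day_step

        rows.append((state.time, state.interior_temp, ambient,
                     last_indoor if is_night else np.nan,
                     last_outdoor if is_night else np.nan,
                     state.electric_heater_on, state.vent_open, is_night, fault))

        if is_night and current_session is not None:
            session_elapsed += dt
            if session_elapsed >= config.log_interval - 1e-9:
                session_elapsed = 0.0
                if last_indoor is not None and last_outdoor is not None:
                    current_session.append(LogRecord(
                        timestamp=state.time + timedelta(seconds=dt),
                        indoor_temp=last_indoor,
                        outdoor_temp=last_outdoor,
                        heater_status="ON" if state.electric_heater_on else "OFF",
                    ))

        state = thermal_step(state, ambient, params, spec, dt)

    trace = pd.DataFrame(rows, columns=[
        "time", "interior_temp", "ambient_temp", "measured_indoor",
        "measured_outdoor", "heater_on", "vent_open", "night", "fault",
    ])
    sessions = [s for s in sessions if s]
    return ControllerRun(sessions=sessions, trace=trace, fault_count=fault_count)


def _format_record(rec: LogRecord) -> str:
    return (f"{rec.timestamp.strftime(_TS_FORMAT)},"
            f"{rec.indoor_temp:.3f},{rec.outdoor_temp:.3f},{rec.heater_status}")


def write_log(sessions: Iterable[Iterable[LogRecord]], path) -> None:
    """Write controller sessions in the device's CSV dialect.

    No header; rows are ``timestamp,indoor,outdoor,status`` with
    temperatures at millikelvin precision; a blank line precedes each
    session, mirroring the device appending a blank line at boot.
    """
    lines: list[str] = []
    for session in sessions:
        records = list(session)
        if not records:
            continue
        lines.append("")
        lines.extend(_format_record(r) for r in records)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_log(path) -> list[list[LogRecord]]:
    """Parse a controller log back into sessions of records.

    Blank lines delimit sessions; consecutive blanks never yield empty
    sessions.  ``write_log(read_log(p), q)`` reproduces the file byte for
    byte.
    """
    sessions: list[list[LogRecord]] = []
    current: list[LogRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            if current:
                sessions.append(current)
                current = []
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise LogParseError(f"expected 4 fields, got {len(parts)}", lineno)
        try:
            ts = datetime.strptime(parts[0], _TS_FORMAT)
            indoor = float(parts[1])
            outdoor = float(parts[2])
        except ValueError as exc:
            raise LogParseError(str(exc), lineno) from exc
        if parts[3] not in ("ON", "OFF"):
            raise LogParseError(f"invalid heater status {parts[3]!r}", lineno)
        current.append(LogRecord(ts, indoor, outdoor, parts[3]))
    if current:
        sessions.append(current)
    return sessions
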