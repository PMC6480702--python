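import dataclasses
from datetime import datetime, time

import numpy as np
import pytest

from heattent.errors import ConfigError, LogParseError
from heattent.schedule import NightWindow
from heattent.tent_thermal import steady_state_differential
from heattent.thermostat import (
    SENSOR_FAULT,
    ControlConfig,
    LogRecord,
    SensorFault,
    SensorSpec,
    decide,
    read_sensor,
    read_log,
    run_controller,
    write_log,
)


class TestDecide:
    @pytest.mark.parametrize(
        "indoor, outdoor, expected",
        [
            (18.0, 14.5, True),   # differential 3.5 < 4 → heat
            (19.0, 14.5, False),  # differential 4.5 > 4 → off
            (10.0, 14.5, True),   # tent colder than ambient → heat
        ],
    )
    def test_bang_bang_rule(self, control_config, indoor, outdoor, expected):
        for prior in (True, False):
            assert decide(indoor, outdoor, control_config, prior) is expected

    @pytest.mark.parametrize("prior", [True, False])
    def test_exact_setpoint_retains_previous_command(self, control_config, prior):
        assert decide(18.5, 14.5, control_config, prior) is prior

    def test_hysteresis_band_widens_dead_zone(self):
        config = ControlConfig(hysteresis_band=1.0)
        assert decide(17.0, 14.0, config, False) is True    # 3.0 < 3.5
        assert decide(19.0, 14.0, config, True) is False    # 5.0 > 4.5
        for prior in (True, False):                          # inside the band
            assert decide(18.2, 14.0, config, prior) is prior

    def test_nonfinite_input_rejected(self, control_config):
        with pytest.raises(Exception):
            decide(float("nan"), 14.0, control_config, False)


class TestReadSensor:
    def test_perfect_sensor_returns_truth(self):
        rng = np.random.default_rng(0)
        spec = SensorSpec(accuracy=0.0, resolution=0.0)
        assert read_sensor(21.375, spec, rng) == 21.375

    def test_error_bounded_by_accuracy(self):
        rng = np.random.default_rng(1)
        spec = SensorSpec(accuracy=0.5, resolution=0.0)
        errors = [read_sensor(20.0, spec, rng) - 20.0 for _ in range(2000)]
        assert max(abs(e) for e in errors) <= 0.5
        assert max(abs(e) for e in errors) > 0.3  # errors actually span the bound

    def test_quantized_to_resolution(self):
        rng = np.random.default_rng(2)
        spec = SensorSpec(accuracy=0.5, resolution=0.0625)
        for _ in range(100):
            value = read_sensor(20.0, spec, rng)
            assert (value / 0.0625) == pytest.approx(round(value / 0.0625), abs=1e-9)

    def test_fault_fraction_matches_failure_rate(self):
        rng = np.random.default_rng(3)
        spec = SensorSpec(failure_rate=0.1)
        n = 10_000
        faults = sum(isinstance(read_sensor(20.0, spec, rng), SensorFault)
                     for _ in range(n))
        assert 0.08 <= faults / n <= 0.12  # binomial 99% interval around 0.1

    def test_invalid_failure_rate_rejected(self):
        with pytest.raises(ConfigError):
            SensorSpec(failure_rate=1.0)


class TestLogDialect:
    @staticmethod
    def _records(start_hour, n):
        return [
            LogRecord(datetime(2024, 5, 20, start_hour, i), 18.0 + i, 14.5, "ON")
            for i in range(n)
        ]

    def test_empty_log_round_trip(self, tmp_path):
        path = tmp_path / "log.csv"
        write_log([], path)
        assert path.read_text() == ""
        assert read_log(path) == []

    def test_two_sessions_layout_and_round_trip(self, tmp_path):
        sessions = [self._records(20, 3), self._records(22, 3)]
        path = tmp_path / "log.csv"
        write_log(sessions, path)
        text = path.read_text()
        lines = text.splitlines()
        assert len([ln for ln in lines if ln.strip()]) == 6   # data rows
        assert len([ln for ln in lines if not ln.strip()]) == 2  # session delimiters
        assert lines[0] == ""  # blank line precedes each session

        back = read_log(path)
        assert [len(s) for s in back] == [3, 3]
        path2 = tmp_path / "log2.csv"
        write_log(back, path2)
        assert path2.read_bytes() == path.read_bytes()

    def test_consecutive_blank_lines_never_create_empty_sessions(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("\n\n\n2024-05-20 20:00:00,18.000,14.500,ON\n\n\n")
        sessions = read_log(path)
        assert [len(s) for s in sessions] == [1]

    @pytest.mark.parametrize("row", [
        "2024-05-20 20:00:00,18.0,14.5",          # missing field
        "not-a-time,18.0,14.5,ON",                # bad timestamp
        "2024-05-20 20:00:00,hot,14.5,ON",        # bad float
        "2024-05-20 20:00:00,18.0,14.5,MAYBE",    # bad status
    ])
    def test_malformed_rows_report_line_number(self, tmp_path, row):
        path = tmp_path / "log.csv"
        path.write_text("\n" + row + "\n")
        with pytest.raises(LogParseError) as exc:
            read_log(path)
        assert exc.value.line_number == 2


class TestClosedLoop:
    def test_no_heater_means_no_differential(self, one_day_weather, tent_spec,
                                             thermal_params, control_config,
                                             perfect_sensor):
        cold = dataclasses.replace(
            tent_spec, electric_heater_output=0.0,
            propane_output_by_setting=dict(tent_spec.propane_output_by_setting))
        run = run_controller(one_day_weather, cold, thermal_params, control_config,
                             perfect_sensor, perfect_sensor, seed=0,
                             propane_setting="off")
        assert abs(run.mean_night_differential()) < 0.2

    def test_oversized_heater_regulates_at_setpoint(self, one_day_weather,
                                                    oversized_tent, thermal_params,
                                                    control_config, perfect_sensor):
        run = run_controller(one_day_weather, oversized_tent, thermal_params,
                             control_config, perfect_sensor, perfect_sensor,
                             seed=0, propane_setting="off")
        assert run.mean_night_differential() == pytest.approx(4.0, abs=0.3)

    def test_undersized_heater_saturates_at_steady_state(self, one_day_weather,
                                                         tent_spec, thermal_params,
                                                         control_config,
                                                         perfect_sensor):
        run = run_controller(one_day_weather, tent_spec, thermal_params,
                             control_config, perfect_sensor, perfect_sensor,
                             seed=0, propane_setting="off")
        expected = steady_state_differential(
            thermal_params, tent_spec.electric_heater_output)
        assert run.mean_night_differential() == pytest.approx(expected, rel=0.05)
        assert run.night_duty_cycle() > 0.99

    def test_no_actuation_outside_night_window(self, one_day_weather, tent_spec,
                                               thermal_params, control_config,
                                               perfect_sensor):
        run = run_controller(one_day_weather, tent_spec, thermal_params,
                             control_config, perfect_sensor, perfect_sensor, seed=0)
        day = run.trace[~run.trace["night"]]
        assert not day["heater_on"].any()
        assert day["vent_open"].all()

    def test_safety_heater_off_above_setpoint(self, one_day_weather, oversized_tent,
                                              thermal_params, control_config,
                                              perfect_sensor):
        run = run_controller(one_day_weather, oversized_tent, thermal_params,
                             control_config, perfect_sensor, perfect_sensor,
                             seed=0, propane_setting="off")
        night = run.trace[run.trace["night"]].dropna(subset=["measured_indoor"])
        measured_diff = night["measured_indoor"] - night["measured_outdoor"]
        above = night[measured_diff > control_config.setpoint_differential + 1e-9]
        assert not above["heater_on"].any()

    def test_logging_cadence_is_log_interval(self, one_day_weather, tent_spec,
                                             thermal_params, control_config,
                                             perfect_sensor):
        run = run_controller(one_day_weather, tent_spec, thermal_params,
                             control_config, perfect_sensor, perfect_sensor, seed=0)
        for session in run.sessions:
            gaps = np.diff([r.timestamp.timestamp() for r in session])
            assert np.all(np.abs(gaps - control_config.log_interval) <= 2.0)

    def test_twelve_hour_night_yields_720_records(self, tent_spec, thermal_params,
                                                  control_config, perfect_sensor):
        from heattent.weather_synth import generate_weather
        weather = generate_weather(seed=4, n_days=1, noise_sd=0.0)
        night = NightWindow(start=time(18, 0), end=time(6, 0))
        run = run_controller(weather, tent_spec, thermal_params, control_config,
                             perfect_sensor, perfect_sensor, night=night, seed=0)
        assert len(run.sessions) == 1
        assert len(run.sessions[0]) == 720

    def test_fault_freezes_heater_command(self, one_day_weather, tent_spec,
                                          thermal_params, control_config):
        flaky = SensorSpec(accuracy=0.0, resolution=0.0, failure_rate=0.3)
        perfect = SensorSpec(accuracy=0.0, resolution=0.0)
        run = run_controller(one_day_weather, tent_spec, thermal_params,
                             control_config, flaky, perfect, seed=5)
        night = run.trace[run.trace["night"]].reset_index(drop=True)
        assert run.fault_count > 0
        fault_rows = night.index[night["fault"]]
        for i in fault_rows:
            if i == 0:
                continue
            assert night.loc[i, "heater_on"] == night.loc[i - 1, "heater_on"]

    def test_reproducible_under_fixed_seed(self, one_day_weather, tent_spec,
                                           thermal_params, control_config):
        noisy = SensorSpec(accuracy=0.5, resolution=0.0625, failure_rate=0.01)
        runs = [run_controller(one_day_weather, tent_spec, thermal_params,
                               control_config, noisy, noisy, seed=9)
                for _ in range(2)]
        assert runs[0].sessions == runs[1].sessions
        assert runs[0].trace.equals(runs[1].trace)


def test_sensor_fault_sentinel_prints_as_sensor():
    assert repr(SENSOR_FAULT) == "SENSOR"
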