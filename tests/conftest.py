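import dataclasses

import pytest

from heattent.heat_sizing import TentSpec
from heattent.tent_thermal import ThermalParams
from heattent.thermostat import ControlConfig, SensorSpec
from heattent.weather_synth import generate_weather


@pytest.fixture
def tent_spec():
    return TentSpec()


@pytest.fixture
def thermal_params():
    """Default tent calibrated so full capacity (29,065 BTU/h) holds 4 °C."""
    return ThermalParams()


@pytest.fixture
def perfect_sensor():
    return SensorSpec(accuracy=0.0, resolution=0.0, failure_rate=0.0)


@pytest.fixture
def control_config():
    return ControlConfig()


@pytest.fixture(scope="session")
def one_day_weather():
    """One day of smooth synthetic weather covering a single night."""
    return generate_weather(seed=11, n_days=1, noise_sd=0.2)


@pytest.fixture
def oversized_tent(tent_spec):
    """Tent whose electric heater alone is 5× the calibrated total load."""
    return dataclasses.replace(
        tent_spec,
        electric_heater_output=5 * 29_065.0,
        propane_output_by_setting=dict(tent_spec.propane_output_by_setting),
    )
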