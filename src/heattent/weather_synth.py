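"""Seeded synthetic ambient weather for driving the tent simulator.

Generates diurnal temperature / relative-humidity (and optionally PAR)
series resembling late-spring continental-plains conditions: a skewed
daily temperature cycle with its minimum near dawn and maximum in the
mid-afternoon, smooth AR(1) weather noise, RH moving in anti-phase with
temperature, and PAR as a daylight half-sine.

All randomness is drawn from a single ``numpy`` generator seeded by the
caller, so identical seed + parameters reproduce the series bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["WeatherSeries", "generate_weather"]

#: AR(1) coefficient of the temperature noise at a 1-minute step.
AR1_COEFF = 0.9


@dataclass
class WeatherSeries:
    """Uniformly sampled ambient conditions on a wall-clock grid.

    ``frame`` holds a ``DatetimeIndex`` (constant step, local clock, no
    timezone) and columns ``temp_c``, ``rh_pct`` and ``par`` (µmol photons
    m⁻² s⁻¹; zero at night).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"temp_c", "rh_pct", "par"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigError(f"weather frame missing columns: {sorted(missing)}")
        idx = self.frame.index
        if len(idx) >= 2:
            steps = np.diff(idx.view("int64"))
            if not (steps > 0).all() or len(set(steps)) != 1:
                raise ConfigError("timestamps must be strictly increasing with constant step")
        rh = self.frame["rh_pct"].to_numpy()
        if ((rh < 0) | (rh > 100)).any():
            raise ConfigError("RH outside [0, 100]")
        if (self.frame["par"].to_numpy() < 0).any():
            raise ConfigError("PAR must be non-negative")

    @property
    def step_minutes(self) -> float:
        idx = self.frame.index
        return float((idx[1] - idx[0]).total_seconds() / 60.0)

    def temp_at(self, when) -> float:
        """Ambient temperature at an arbitrary instant, linearly interpolated."""
        t = self.frame.index.view("int64")
        q = pd.Timestamp(when).value
        if q < t[0] or q > t[-1]:
            raise ConfigError(f"{when} outside weather coverage")
        return float(np.interp(q, t, self.frame["temp_c"].to_numpy()))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%dT%H:%M:%S"))
        out.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        df = df.set_index("timestamp")
        if "par" not in df.columns:
            df["par"] = 0.0
        return cls(df)


def _diurnal_cycle(hours: np.ndarray, mean: float, amplitude: float,
                   min_hour: float, max_hour: float) -> np.ndarray:
    """Skewed daily cycle: cosine rise min→max, cosine fall max→min(+24 h)."""
    h = np.mod(hours, 24.0)
    rise_len = (max_hour - min_hour) % 24.0
    fall_len = 24.0 - rise_len
    out = np.empty_like(h)
    rising = (h >= min_hour) & (h < max_hour)
    out[rising] = -np.cos(np.pi * (h[rising] - min_hour) / rise_len)
    hf = np.mod(h[~rising] - max_hour, 24.0)
    out[~rising] = np.cos(np.pi * hf / fall_len)
    return mean + amplitude * out


def generate_weather(
    seed: int,
    n_days: int = 3,
    mean_temp: float = 15.0,
    amplitude: float = 8.0,
    rh_mean: float = 65.0,
    rh_amplitude: float = 20.0,
    noise_sd: float = 0.5,
    step: float = 1.0,
    start: datetime | str = "2024-05-20 12:00:00",
    min_hour: float = 6.0,
    max_hour: float = 16.0,
    par_peak: float = 1400.0,
    dawn_hour: float = 6.0,
    dusk_hour: float = 20.0,
) -> WeatherSeries:
    """Generate a seeded synthetic weather series.

    Parameters
    ----------
    seed : int
        Seed for the AR(1) noise stream.
    n_days : int
        Number of 24-h days to generate.
    mean_temp, amplitude : float
        Daily mean and half-range of the temperature cycle, °C.  The
        cycle minimum falls at ``min_hour`` and the maximum at
        ``max_hour`` (local clock).
    rh_mean, rh_amplitude : float
        RH cycle in %, in exact anti-phase with temperature and clipped
        to [0, 100].
    noise_sd : float
        Stationary standard deviation of the AR(1) temperature noise, °C.
    step : float
        Sampling step in minutes.
    par_peak : float
        Midday PAR peak, µmol photons m⁻² s⁻¹; PAR is a half-sine between
        ``dawn_hour`` and ``dusk_hour`` and zero at night.
    """
    if step <= 0:
        raise ConfigError(f"step must be positive, got {step}")
    if n_days < 1:
        raise ConfigError(f"n_days must be >= 1, got {n_days}")
    if amplitude < 0 or noise_sd < 0:
        raise ConfigError("amplitude and noise_sd must be non-negative")

    n = int(round(n_days * 24 * 60 / step))
    index = pd.date_range(pd.Timestamp(start), periods=n, freq=pd.Timedelta(minutes=step))
    hours = index.hour + index.minute / 60.0 + index.second / 3600.0
    hours = np.asarray(hours, dtype=float)

    temp = _diurnal_cycle(hours, mean_temp, amplitude, min_hour, max_hour)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        # AR(1) coefficient is specified at a 1-min step; rescale so the
        # process keeps the same decorrelation time at other steps.
        phi = AR1_COEFF ** step
        innov_sd = noise_sd * np.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, noise_sd)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]
        temp = temp + noise

    # RH in exact anti-phase with the noiseless temperature cycle.
    if amplitude > 0:
        cycle = _diurnal_cycle(hours, 0.0, 1.0, min_hour, max_hour)
    else:
        cycle = np.zeros(n)
    rh = np.clip(rh_mean - rh_amplitude * cycle, 0.0, 100.0)

    day = (hours >= dawn_hour) & (hours < dusk_hour)
    par = np.zeros(n)
    par[day] = par_peak * np.sin(np.pi * (hours[day] - dawn_hour) / (dusk_hour - dawn_hour))
    par = np.clip(par, 0.0, None)

    frame = pd.DataFrame({"temp_c": temp, "rh_pct": rh, "par": par}, index=index)
    frame.index.name = "timestamp"
    return WeatherSeries(frame)
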