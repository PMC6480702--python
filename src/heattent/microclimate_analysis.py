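"""Microclimate statistics from heterogeneous sensor streams.

Covers the downstream analysis of a heat-tent experiment: aligning
sensor streams logged at different cadences (a 15-min HOBO logger
against a 1-min controller log) onto a common grid, interior−exterior
temperature differentials split by night/day window, vapor pressure
deficit (VPD), and mean diurnal profiles with their peak and
zero-crossing clock times.

VPD uses the Tetens (Magnus-form) saturation vapor pressure standard in
agronomy:

    es(T) = 0.6108 · exp(17.27 T / (T + 237.3))   [kPa, T in °C]
    VPD   = es(T) · (1 − RH/100)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, EmptyWindowError
from .schedule import NightWindow
from .thermostat import LogRecord

__all__ = [
    "AlignedStreams",
    "align",
    "mean_differential",
    "DifferentialStats",
    "vpd",
    "saturation_vapor_pressure",
    "diurnal_profile",
    "DiurnalProfile",
    "log_sessions_to_streams",
    "write_hobo_csv",
    "read_hobo_csv",
]

# Tetens constants (kPa, °C).
TETENS_A = 0.6108
TETENS_B = 17.27
TETENS_C = 237.3

#: Minimum fraction of in-window samples for an unflagged statistic.
COVERAGE_THRESHOLD = 0.8


@dataclass
class AlignedStreams:
    """Sensor streams interpolated onto one shared timestamp grid."""

    frame: pd.DataFrame  # DatetimeIndex grid; one column per stream label

    @property
    def labels(self) -> list[str]:
        return list(self.frame.columns)

    def __getitem__(self, label: str) -> pd.Series:
        return self.frame[label]


def align(
    streams: Mapping[str, pd.Series],
    grid_minutes: float = 1.0,
    max_gap_minutes: float = 60.0,
) -> AlignedStreams:
    """Linearly interpolate streams onto a shared regular grid.

    The grid spans the overlap of all streams.  Grid points bracketed by
    source samples more than ``max_gap_minutes`` apart are left missing
    and excluded from downstream statistics.
    """
    if not streams:
        raise AlignmentError("no streams given")
    starts = [s.index[0] for s in streams.values()]
    ends = [s.index[-1] for s in streams.values()]
    lo, hi = max(starts), min(ends)
    if lo > hi:
        raise AlignmentError(f"streams have no temporal overlap ({lo} > {hi})")

    step = pd.Timedelta(minutes=grid_minutes)
    grid = pd.date_range(lo.ceil(step), hi.floor(step), freq=step)
    if len(grid) == 0:
        raise AlignmentError("overlap shorter than one grid step")
    grid_ns = grid.view("int64")
    max_gap_ns = max_gap_minutes * 60e9

    cols = {}
    for label, series in streams.items():
        s = series.dropna().sort_index()
        t = np.asarray(s.index.view("int64"))
        v = s.to_numpy(dtype=float)
        out = np.interp(grid_ns, t, v)
        # Mask grid points whose bracketing source samples are too far apart.
        right = np.searchsorted(t, grid_ns, side="left").clip(1, len(t) - 1)
        gap = t[right] - t[right - 1]
        out = np.where(gap > max_gap_ns, np.nan, out)
        out = np.where((grid_ns < t[0]) | (grid_ns > t[-1]), np.nan, out)
        cols[label] = out

    frame = pd.DataFrame(cols, index=grid)
    frame.index.name = "timestamp"
    return AlignedStreams(frame)


@dataclass(frozen=True)
class DifferentialStats:
    """Mean, SD and sample count of a stream differential in one window."""

    mean: float
    sd: float
    n: int
    coverage: float
    flagged: bool  # True when window coverage is below the threshold


def mean_differential(
    aligned: AlignedStreams,
    a: str,
    b: str,
    window: str = "all",
    night: NightWindow = NightWindow(),
) -> DifferentialStats:
    """Mean of ``a − b`` over the requested window (night / day / all).

    Statistics use pairwise-complete samples only; the result is flagged
    when fewer than 80% of in-window grid points are complete.
    """
    if window not in ("night", "day", "all"):
        raise DomainError(f"window must be night/day/all, got {window!r}")
    frame = aligned.frame
    mask = np.ones(len(frame), dtype=bool)
    if window != "all":
        night_mask = night.mask(frame.index)
        mask = night_mask if window == "night" else ~night_mask
    if not mask.any():
        raise EmptyWindowError(f"no samples in {window} window")
    diff = (frame[a] - frame[b]).to_numpy()[mask]
    complete = np.isfinite(diff)
    n = int(complete.sum())
    if n == 0:
        raise EmptyWindowError(f"no pairwise-complete samples in {window} window")
    coverage = n / mask.sum()
    values = diff[complete]
    return DifferentialStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n > 1 else 0.0,
        n=n,
        coverage=float(coverage),
        flagged=coverage < COVERAGE_THRESHOLD,
    )


def saturation_vapor_pressure(temp_c):
    """Tetens saturation vapor pressure es(T) in kPa for T in °C."""
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < -40) or np.any(t > 60):
        raise DomainError("temperature outside [-40, 60] °C")
    es = TETENS_A * np.exp(TETENS_B * t / (t + TETENS_C))
    return float(es) if np.isscalar(temp_c) else es


def vpd(temp_c, rh_pct):
    """Vapor pressure deficit in kPa from air temperature (°C) and RH (%)."""
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise DomainError("RH outside [0, 100]")
    es = saturation_vapor_pressure(temp_c)
    out = es * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(temp_c) and np.isscalar(rh_pct) else out


@dataclass
class DiurnalProfile:
    """Mean value per clock-time bin, with peak and zero-crossing times."""

    curve: pd.Series  # indexed by minutes past midnight of the bin start
    peak_time: pd.Timedelta  # clock time of the maximum bin mean
    peak_value: float
    zero_crossing: pd.Timedelta | None  # first sign change after the peak


def diurnal_profile(stream: pd.Series, bin_minutes: float = 5.0) -> DiurnalProfile:
    """Average a (difference) series onto a 24-h clock and locate features.

    Requires at least one full day of coverage.  The zero crossing is the
    first bin after the peak whose mean changes sign relative to the peak
    (scanning the clock circularly); ``None`` when the profile never
    crosses zero.
    """
    s = stream.dropna()
    if len(s) < 2 or (s.index[-1] - s.index[0]) < pd.Timedelta(hours=24):
        raise DomainError("diurnal profile requires at least one full day of data")
    minutes = (s.index.hour * 60 + s.index.minute + s.index.second / 60.0)
    bins = (np.floor_divide(minutes, bin_minutes) * bin_minutes).astype(float)
    curve = s.groupby(bins).mean()
    curve.index.name = "clock_minutes"

    peak_idx = int(np.argmax(curve.to_numpy()))
    peak_minutes = float(curve.index[peak_idx])
    peak_value = float(curve.iloc[peak_idx])

    values = curve.to_numpy()
    n = len(values)
    crossing = None
    if peak_value != 0:
        sign0 = np.sign(peak_value)
        for k in range(1, n + 1):
            v = values[(peak_idx + k) % n]
            if np.sign(v) == -sign0:
                crossing = pd.Timedelta(minutes=float(curve.index[(peak_idx + k) % n]))
                break
    return DiurnalProfile(
        curve=curve,
        peak_time=pd.Timedelta(minutes=peak_minutes),
        peak_value=peak_value,
        zero_crossing=crossing,
    )


def log_sessions_to_streams(sessions: list[list[LogRecord]]) -> dict[str, pd.Series]:
    """Convert controller log sessions into interior/exterior streams."""
    if not sessions:
        return {}
    records = [r for session in sessions for r in session]
    idx = pd.DatetimeIndex([r.timestamp for r in records])
    return {
        "pi_interior": pd.Series([r.indoor_temp for r in records], index=idx),
        "pi_exterior": pd.Series([r.outdoor_temp for r in records], index=idx),
    }


def write_hobo_csv(frame: pd.DataFrame, path) -> None:
    """Write a HOBO-style export: header plus timestamp, temp, RH rows."""
    out = frame.copy()
    out.insert(0, "timestamp", out.index.strftime("%Y-%m-%d %H:%M:%S"))
    out.to_csv(path, index=False, float_format="%.3f")


def read_hobo_csv(path) -> pd.DataFrame:
    """Read a HOBO-style CSV back into a DatetimeIndex frame."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df.set_index("timestamp")
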