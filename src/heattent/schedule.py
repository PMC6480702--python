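"""Night-window schedule shared by the controller and the analytics.

The heat-stress treatment runs on local wall-clock time: tents are sealed
and heating starts in the evening and everything is opened back up before
dawn, so the night window wraps midnight.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time

import numpy as np
import pandas as pd

__all__ = ["NightWindow"]


@dataclass(frozen=True)
class NightWindow:
    """Half-open nightly window [start, end) on the local clock.

    Defaults match the field schedule: sealing began at 19:15 and the
    tents were opened at 05:45, so the window wraps midnight.  A window
    with ``start == end`` has zero length (never night).
    """

    start: time = time(19, 15)
    end: time = time(5, 45)

    def contains(self, ts: datetime | time) -> bool:
        t = ts.time() if isinstance(ts, datetime) else ts
        if self.start == self.end:
            return False
        if self.start < self.end:
            return self.start <= t < self.end
        return t >= self.start or t < self.end

    def mask(self, index: pd.DatetimeIndex) -> np.ndarray:
        """Boolean array marking index entries inside the night window."""
        minutes = index.hour * 60 + index.minute + index.second / 60.0
        s = self.start.hour * 60 + self.start.minute
        e = self.end.hour * 60 + self.end.minute
        if s == e:
            return np.zeros(len(index), dtype=bool)
        if s < e:
            return np.asarray((minutes >= s) & (minutes < e))
        return np.asarray((minutes >= s) | (minutes < e))

    @property
    def duration_hours(self) -> float:
        s = self.start.hour + self.start.minute / 60.0
        e = self.end.hour + self.end.minute / 60.0
        if s == e:
            return 0.0
        return (e - s) % 24.0
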