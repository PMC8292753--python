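"""Core containers shared across the pipeline.

The analysis operates on *observation days*: 24 h windows anchored at 17.00
local civil time and ending at 16.55 the following calendar day. At the
5-minute logger cadence an observation day has 1440/5 = 288 slots; slot 0 is
17.00 and slot 287 is 16.55 (+1 day). All phase timings are expressed in
*decimal observation hours*, i.e. hours elapsed since the 17.00 anchor
(19.45 clock time -> 2.75 h).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Clock hour at which every observation day starts.
DAY_ANCHOR_HOUR = 17

#: Minutes in an observation day.
DAY_MINUTES = 1440

#: Canonical season labels, in within-study chronological order.
SEASONS = ("summer", "autumn", "winter", "spring")


def clock_to_observation_hours(clock_hours: float) -> float:
    """Convert a civil clock time (decimal hours) to decimal observation hours.

    Observation time starts at 17.00, so 19.75 (i.e. 19:45) -> 2.75 and
    2.0 (02:00) -> 9.0.
    """
    return (clock_hours - DAY_ANCHOR_HOUR) % 24.0


def observation_to_clock_hours(obs_hours: float) -> float:
    """Inverse of :func:`clock_to_observation_hours`."""
    return (obs_hours + DAY_ANCHOR_HOUR) % 24.0


@dataclass
class SensorSeries:
    """A time-stamped sequence of readings from one logger.

    Parameters
    ----------
    source_id : str
        Logger identifier (participant id or outdoor site id).
    kind : {"lux", "temperature"}
        What the logger measures.
    timestamps : pandas.DatetimeIndex
        Strictly increasing local civil instants.
    values : numpy.ndarray
        Readings; non-negative for ``kind="lux"``, degrees C otherwise.
    cadence_min : float
        Nominal sampling interval in minutes (5 for individuals, 3 for
        outdoor sites), inferred as the modal inter-reading gap when read
        from file.
    """

    source_id: str
    kind: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    cadence_min: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("lux", "temperature"):
            raise ValueError(f"unknown sensor kind {self.kind!r}")
        if self.cadence_min <= 0:
            raise ValueError("cadence must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ObservationDay:
    """One 17.00-anchored 24 h grid of values for one source.

    ``values`` has length ``1440 / cadence_min`` (288 at 5-min cadence) with
    NaN marking empty slots. ``partial`` flags a trailing day whose source
    series ended before 16.55; partial days are kept for time-of-day
    averages but excluded from daily AUC totals.
    """

    source_id: str
    kind: str
    season: str
    day_index: int
    start: pd.Timestamp
    values: np.ndarray
    cadence_min: float = 5.0
    partial: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = DAY_MINUTES / self.cadence_min
        if len(self.values) != int(expected):
            raise ValueError(
                f"day grid must have {int(expected)} slots at "
                f"{self.cadence_min}-min cadence, got {len(self.values)}"
            )

    @property
    def n_slots(self) -> int:
        return len(self.values)

    @property
    def slot_minutes(self) -> np.ndarray:
        """Minutes after 17.00 for each slot."""
        return np.arange(self.n_slots) * self.cadence_min

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class SolarTimes:
    """Sunrise/sunset for one date and site, in local civil time."""

    date: pd.Timestamp
    latitude: float
    longitude: float
    sunrise: pd.Timestamp
    sunset: pd.Timestamp

    @property
    def photoperiod_hours(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0

    @property
    def sunrise_hours(self) -> float:
        """Sunrise as decimal clock hours."""
        t = self.sunrise
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    @property
    def sunset_hours(self) -> float:
        t = self.sunset
        return t.hour + t.minute / 60.0 + t.second / 3600.0


@dataclass
class PhaseRecord:
    """Per-observation-day maximum wrist-temperature timing."""

    source_id: str
    season: str
    day_index: int
    max_timing_h: float  # decimal observation hours in [0, 24)
    max_value_c: float
    n_imputed: int = 0
    n_masked: int = 0


def days_to_frame(days: list) -> pd.DataFrame:
    """Tidy long-format table of an ObservationDay list.

    Columns: source_id, season, day_index, slot_time (minutes after 17.00),
    value. NaN slots are written as empty values so the table round-trips.
    """
    frames = []
    for d in days:
        frames.append(
            pd.DataFrame(
                {
                    "source_id": d.source_id,
                    "season": d.season,
                    "day_index": d.day_index,
                    "slot_time": d.slot_minutes,
                    "value": d.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
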