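"""Read logger CSVs and align readings onto the 17.00-anchored day grid.

The file contract is deliberately plain: a two-column delimited text file
with header ``timestamp,value``, ISO 8601 local civil timestamps, one file
per sensor per season. A manifest (YAML or JSON) maps files to source ids,
sensor kinds, seasons and site coordinates.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError, OrderingError
from .types import DAY_ANCHOR_HOUR, DAY_MINUTES, ObservationDay, SensorSeries


def read_sensor_csv(path, kind: str, source_id: str | None = None) -> SensorSeries:
    """Parse a ``timestamp,value`` CSV into a :class:`SensorSeries`.

    The cadence is inferred as the modal inter-reading gap in minutes.

    Raises
    ------
    EmptyInputError
        If the file holds no data rows.
    FormatError
        If a timestamp or value fails to parse (the message names the line).
    OrderingError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path} contains no readings")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["timestamp", "value"]:
        raise FormatError(f"{path}: expected header 'timestamp,value', got {list(df.columns)}")

    ts = pd.to_datetime(df.iloc[:, 0], format="ISO8601", errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: one for the header row, one for 1-based line numbering
        raise FormatError(
            f"{path}: unparseable timestamp {df.iloc[bad[0], 0]!r} on line {bad[0] + 2}"
        )
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    badv = np.flatnonzero(vals.isna().to_numpy() & df.iloc[:, 1].notna().to_numpy())
    if badv.size:
        raise FormatError(
            f"{path}: unparseable value {df.iloc[badv[0], 1]!r} on line {badv[0] + 2}"
        )

    tvals = pd.DatetimeIndex(ts)
    diffs = np.diff(tvals.asi8)
    if (diffs <= 0).any():
        i = int(np.flatnonzero(diffs <= 0)[0])
        raise OrderingError(
            f"{path}: timestamps not strictly increasing at line {i + 3} "
            f"({tvals[i + 1]} follows {tvals[i]})"
        )

    if len(tvals) > 1:
        gaps_min = np.round(diffs / 60e9, 6)
        uniq, counts = np.unique(gaps_min, return_counts=True)
        cadence = float(uniq[np.argmax(counts)])
    else:
        cadence = 5.0
    if kind == "lux" and (vals.to_numpy(dtype=float) < 0).any():
        raise FormatError(f"{path}: negative lux reading")
    return SensorSeries(
        source_id=source_id or path.stem,
        kind=kind,
        timestamps=tvals,
        values=vals.to_numpy(dtype=float),
        cadence_min=cadence,
    )


def _first_anchor(t0: pd.Timestamp) -> pd.Timestamp:
    """17.00 on the first day of sampling.

    Readings earlier in that calendar day are dropped; a series starting
    after 17.00 keeps its leading slots missing rather than shifting the
    grid to the next day.
    """
    return t0.normalize() + pd.Timedelta(hours=DAY_ANCHOR_HOUR)


def to_observation_days(
    series: SensorSeries,
    season: str = "",
    target_cadence_min: float | None = None,
) -> list[ObservationDay]:
    """Grid a series onto 17.00-anchored observation days.

    Readings before the first 17.00 are dropped. Each retained reading is
    snapped to the nearest slot centre; an exact tie between two slots goes
    to the earlier slot. When two readings snap to the same slot (only
    possible when readings are denser than the slot grid, e.g. 3-min outdoor
    data regridded onto the 5-min grid), the reading closest to the slot
    centre wins, so outdoor and individual metrics share one window engine.
    The trailing partial day is retained and flagged ``partial``.
    """
    if len(series) == 0:
        raise EmptyInputError("cannot grid an empty series")
    cadence = float(target_cadence_min or series.cadence_min)
    n_slots = int(round(DAY_MINUTES / cadence))
    anchor = _first_anchor(series.timestamps[0])

    offsets_s = (series.timestamps.asi8 - anchor.value) / 1e9
    keep = offsets_s >= 0
    offsets_s = offsets_s[keep]
    values = series.values[keep]
    if offsets_s.size == 0:
        raise EmptyInputError("no readings at or after the first 17.00 anchor")

    cad_s = cadence * 60.0
    # nearest slot, exact halfway ties to the earlier slot
    slot_global = np.ceil(offsets_s / cad_s - 0.5).astype(np.int64)
    day_idx, slot = np.divmod(slot_global, n_slots)
    dist = np.abs(offsets_s - slot_global * cad_s)

    n_days = int(day_idx.max()) + 1
    grid = np.full((n_days, n_slots), np.nan)
    best = np.full((n_days, n_slots), np.inf)
    # iterate in time order; closest reading to each slot centre wins
    for d, s, v, dd in zip(day_idx, slot, values, dist):
        if dd < best[d, s]:
            grid[d, s] = v
            best[d, s] = dd

    last = series.timestamps[-1]
    days = []
    for d in range(n_days):
        start = anchor + pd.Timedelta(days=d)
        day_end = start + pd.Timedelta(minutes=(n_slots - 1) * cadence)
        days.append(
            ObservationDay(
                source_id=series.source_id,
                kind=series.kind,
                season=season,
                day_index=d,
                start=start,
                values=grid[d],
                cadence_min=cadence,
                partial=last < day_end,
            )
        )
    return days


@dataclass
class ManifestEntry:
    """One sensor file registered in a cohort manifest."""

    path: Path
    source_id: str
    kind: str
    season: str
    role: str = "individual"  # or "outdoor"
    latitude: float = 40.85
    longitude: float = -73.93
    utc_offset_hours: float = -5.0
    start_date: str = ""


@dataclass
class Manifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    @classmethod
    def load(cls, path) -> "Manifest":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        entries = []
        for e in data["entries"]:
            e = dict(e)
            e["path"] = (path.parent / e["path"]).resolve()
            entries.append(ManifestEntry(**e))
        return cls(entries)

    def save(self, path) -> None:
        path = Path(path)
        data = {
            "entries": [
                {
                    "path": str(
                        Path(e.path).relative_to(path.parent)
                        if Path(e.path).is_absolute()
                        else e.path
                    ),
                    "source_id": e.source_id,
                    "kind": e.kind,
                    "season": e.season,
                    "role": e.role,
                    "latitude": e.latitude,
                    "longitude": e.longitude,
                    "utc_offset_hours": e.utc_offset_hours,
                    "start_date": e.start_date,
                }
                for e in self.entries
            ]
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
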