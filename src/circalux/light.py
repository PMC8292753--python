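"""Illuminance transform, windowed trapezoidal AUC, and cohort dispersion.

Light exposure is quantified as the area under the log10-transformed lux
series, integrated by the trapezoidal rule against time in minutes
(unit: log10lux-minutes). The loggers have a 10-lux lower limit of
detection; readings below it are floored to 0 log10lux so that darkness
contributes zero exposure and log(0) never arises.

Windows are resolved on the 17.00-anchored observation-day grid. The day is
treated as a closed 24 h cycle (the 1440-minute endpoint reuses slot 0), so
a constant 1 log10lux day integrates to exactly 1440 log10lux-minutes and
the four fixed 6 h windows tile the day additively. Windows whose clock
bounds straddle the 17.00 anchor wrap across the grid boundary within the
same observation day; because solar times move by under a minute per day,
this is chronologically equivalent to using the neighbouring calendar day's
solar events.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .types import DAY_MINUTES, ObservationDay, SolarTimes, clock_to_observation_hours

#: Logger lower limit of detection, lux.
LOD_LUX = 10.0

#: Longest missing run (minutes) bridged inside a window before the
#: window's AUC is declared missing for the day.
MAX_BRIDGE_MIN = 30.0


def log_illuminance(lux):
    """log10 of illuminance with the below-LOD floor.

    ``lux >= 10`` maps to ``log10(lux)`` (so the 10-lux floor maps to 1);
    anything below the detection limit maps to 0. Accepts scalars or arrays;
    NaN passes through.
    """
    arr = np.asarray(lux, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("illuminance must be non-negative")
    out = np.where(arr >= LOD_LUX, np.log10(np.where(arr >= LOD_LUX, arr, 1.0)), 0.0)
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(lux):
        return float(out)
    return out


@dataclass(frozen=True)
class ExposureWindow:
    """A named temporal window on the observation-day grid.

    ``start``/``end`` are either decimal clock hours or the solar tokens
    ``"sunset"`` (nearest slot) / ``"sunset_hour"`` (sunset rounded to the
    whole clock hour, the "approximate hour of sunset" convention).
    """

    name: str
    start: object
    end: object


#: The nine windows of the analysis. Clock hours; solar tokens resolve per day.
WINDOWS = (
    ExposureWindow("total_day", 17.0, 17.0),
    ExposureWindow("night_sunset_0400", "sunset", 4.0),
    ExposureWindow("daytime_0400_sunset", 4.0, "sunset_hour"),
    ExposureWindow("std_night_2100_0200", 21.0, 2.0),
    ExposureWindow("morning_0400_1159", 4.0, 12.0),
    ExposureWindow("fixed_morning_0500_1100", 5.0, 11.0),
    ExposureWindow("fixed_afternoon_1100_1700", 11.0, 17.0),
    ExposureWindow("fixed_evening_1700_2300", 17.0, 23.0),
    ExposureWindow("fixed_latenight_2300_0500", 23.0, 5.0),
)

WINDOWS_BY_NAME = {w.name: w for w in WINDOWS}

#: Windows feeding the phase-timing regression.
STD_NIGHT = WINDOWS_BY_NAME["std_night_2100_0200"]
STD_MORNING = WINDOWS_BY_NAME["morning_0400_1159"]


def _resolve_bound(bound, solar: SolarTimes | None, cadence_min: float) -> float:
    """Resolve a window bound to minutes after 17.00, snapped to the grid."""
    if isinstance(bound, str):
        if solar is None:
            raise ValueError(f"window bound {bound!r} needs SolarTimes")
        if bound == "sunset":
            clock_h = solar.sunset_hours
        elif bound == "sunset_hour":
            clock_h = round(solar.sunset_hours)
        else:
            raise ValueError(f"unknown solar token {bound!r}")
    else:
        clock_h = float(bound)
    minutes = clock_to_observation_hours(clock_h) * 60.0
    return round(minutes / cadence_min) * cadence_min


def _segment_auc(t: np.ndarray, v: np.ndarray, seg_start: float, seg_end: float,
                 cadence: float):
    """Trapezoid AUC of one non-wrapping segment; NaN if a gap is too long."""
    sel = (t >= seg_start) & (t <= seg_end)
    ts, vs = t[sel], v[sel]
    obs = ~np.isnan(vs)
    if obs.sum() < 2:
        return np.nan
    to, vo = ts[obs], vs[obs]
    # interior gaps are bridged by the trapezoid between flanking observed
    # slots; edge gaps shrink the segment. Either way, a missing run longer
    # than MAX_BRIDGE_MIN makes the segment missing. An interior run of k
    # slots spans k*cadence minutes but leaves an observed-to-observed gap
    # of (k+1)*cadence, hence the extra cadence in the interior check.
    if to[0] - seg_start > MAX_BRIDGE_MIN or seg_end - to[-1] > MAX_BRIDGE_MIN:
        return np.nan
    if np.max(np.diff(to)) - cadence > MAX_BRIDGE_MIN + 1e-9:
        return np.nan
    return float(np.trapezoid(vo, to))


def auc_trapezoid(
    day: ObservationDay,
    window: ExposureWindow,
    solar: SolarTimes | None = None,
) -> float:
    """Trapezoidal AUC of a log10lux observation day over one window.

    Returns NaN (missing, never zero) when the window cannot be evaluated:
    fully missing data, or a missing run longer than 30 minutes inside it.
    """
    cad = day.cadence_min
    start = _resolve_bound(window.start, solar, cad)
    end = _resolve_bound(window.end, solar, cad)
    if end == 0.0:  # a bound falling exactly on the anchor closes the cycle
        end = float(DAY_MINUTES)

    # closed-cycle grid: append the 1440' point carrying slot 0's value
    t = np.concatenate([day.slot_minutes, [DAY_MINUTES]])
    v = np.concatenate([day.values, day.values[:1]])

    if start == end:  # full-day window
        return _segment_auc(t, v, 0.0, DAY_MINUTES, cad)
    if start < end:
        return _segment_auc(t, v, start, end, cad)
    # wraps the 17.00 boundary: two chronologically disjoint segments
    a = _segment_auc(t, v, start, DAY_MINUTES, cad)
    b = _segment_auc(t, v, 0.0, end, cad)
    return a + b


def window_exposures(
    day: ObservationDay,
    solar: SolarTimes | None = None,
    windows=WINDOWS,
) -> dict:
    """AUC for every named window of one observation day.

    Missing-window results propagate as NaN entries.
    """
    return {w.name: auc_trapezoid(day, w, solar) for w in windows}


def exposure_table(days, solar_by_day=None, windows=WINDOWS) -> pd.DataFrame:
    """Tidy per-day AUC table for a list of log10lux observation days.

    Partial trailing days are excluded (daily AUC totals need whole days).
    ``solar_by_day`` maps ``(source_id, season, day_index)`` or is a single
    :class:`SolarTimes` applied to all days.
    """
    rows = []
    for d in days:
        if d.partial:
            continue
        if isinstance(solar_by_day, dict):
            solar = solar_by_day.get((d.source_id, d.season, d.day_index))
        else:
            solar = solar_by_day
        for name, auc in window_exposures(d, solar, windows).items():
            rows.append(
                {
                    "source_id": d.source_id,
                    "season": d.season,
                    "day_index": d.day_index,
                    "window": name,
                    "auc_log10lux_min": auc,
                }
            )
    return pd.DataFrame(rows)


def relative_standard_error(values) -> float:
    """RSE in percent: ``100 * (sd/sqrt(n)) / mean``.

    Raises
    ------
    InsufficientDataError
        For fewer than two values.
    UndefinedStatisticError
        When the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise InsufficientDataError("RSE needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedStatisticError("RSE undefined for zero mean")
    se = arr.std(ddof=1) / np.sqrt(arr.size)
    return float(100.0 * se / mean)


def cohort_summary(exposures: pd.DataFrame, by=("window", "season")) -> pd.DataFrame:
    """Per-group mean, standard error, and RSE of daily AUC values."""

    def _agg(g):
        vals = g["auc_log10lux_min"].dropna()
        n = len(vals)
        mean = vals.mean() if n else np.nan
        se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rse = 100.0 * se / mean if n > 1 and mean != 0 else np.nan
        return pd.Series({"n_days": n, "mean": mean, "se": se, "rse_pct": rse})

    out = exposures.groupby(list(by)).apply(_agg, include_groups=False).reset_index()
    out["n_days"] = out["n_days"].astype(int)
    return out
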