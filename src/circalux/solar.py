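"""Sunrise/sunset from the NOAA solar position equations.

Implements the NOAA General Solar Position Calculations: fractional-year
Fourier expansions for the equation of time and solar declination, and the
hour angle for the standard refraction-corrected zenith of 90.833 degrees.
Accuracy is on the order of a minute at mid-latitudes, which is ample for
windowing light exposure against "approximate" sunrise and sunset.
"""
from __future__ import annotations

import math

import pandas as pd

from .errors import UnsupportedLatitudeError
from .types import SolarTimes

#: Refraction-corrected solar zenith at sunrise/sunset, degrees.
SUNRISE_ZENITH_DEG = 90.833

#: Latitude limit beyond which polar day/night can occur near the solstices.
MAX_ABS_LATITUDE = 66.0


def _fractional_year(date: pd.Timestamp, hour: float = 12.0) -> float:
    doy = date.dayofyear
    year_len = 366 if date.is_leap_year else 365
    return 2.0 * math.pi / year_len * (doy - 1 + (hour - 12.0) / 24.0)


def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )


def _declination_rad(gamma: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def solar_times(
    date,
    latitude: float,
    longitude: float,
    utc_offset_hours: float,
) -> SolarTimes:
    """Sunrise and sunset for ``date`` at a site, in local civil time.

    Parameters
    ----------
    date : date-like
        Calendar date.
    latitude, longitude : float
        Site coordinates in degrees (west longitudes negative).
    utc_offset_hours : float
        Offset of local civil time from UTC (e.g. -5 for EST, -4 for EDT).

    Raises
    ------
    UnsupportedLatitudeError
        If ``|latitude| >= 66`` or the sun does not cross the sunrise zenith
        on that date (polar day/night).
    """
    date = pd.Timestamp(date).normalize()
    if abs(latitude) >= MAX_ABS_LATITUDE:
        raise UnsupportedLatitudeError(
            f"latitude {latitude} is outside the supported band "
            f"(|lat| < {MAX_ABS_LATITUDE})"
        )

    gamma = _fractional_year(date)
    eqtime = _equation_of_time_min(gamma)
    decl = _declination_rad(gamma)

    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(SUNRISE_ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if not -1.0 < cos_ha < 1.0:
        raise UnsupportedLatitudeError(
            f"no sunrise/sunset at latitude {latitude} on {date.date()}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    sunrise_utc_min = 720.0 - 4.0 * (longitude + ha_deg) - eqtime
    sunset_utc_min = 720.0 - 4.0 * (longitude - ha_deg) - eqtime

    base = date  # midnight UTC reference shifted below
    sunrise = base + pd.Timedelta(minutes=sunrise_utc_min + utc_offset_hours * 60.0)
    sunset = base + pd.Timedelta(minutes=sunset_utc_min + utc_offset_hours * 60.0)
    return SolarTimes(
        date=date,
        latitude=latitude,
        longitude=longitude,
        sunrise=sunrise,
        sunset=sunset,
    )
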