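"""Independent reference implementations used only as test oracles.

Kept deliberately separate from the package's algorithms: sun events
come from the closed-form NOAA sunrise equation (Fourier-series
equation of time and declination plus an hour-angle inversion),
whereas the package scans altitudes on a minute grid from a different
position model; distances come from the spherical law of cosines
rather than the haversine form.
"""

from __future__ import annotations

import math
from datetime import date as Date
from datetime import datetime, timedelta, timezone

EARTH_RADIUS_KM = 6371.0


def _noaa_eqtime_decl(day_of_year: int, hour_utc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians), NOAA Fourier fit."""
    gamma = 2.0 * math.pi / 365.0 * (day_of_year - 1 + (hour_utc - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    return eqtime, decl


def _event_minutes(lat: float, lon: float, day: Date, rising: bool) -> float:
    """Minutes after UTC midnight of sunrise/sunset on `day` (NOAA closed form)."""
    doy = day.timetuple().tm_yday
    phi = math.radians(lat)
    minutes = 720.0
    for _ in range(2):  # one refinement pass on the event hour
        eqtime, decl = _noaa_eqtime_decl(doy, minutes / 60.0)
        cos_ha = (
            math.cos(math.radians(90.833)) / (math.cos(phi) * math.cos(decl))
            - math.tan(phi) * math.tan(decl)
        )
        if not -1.0 <= cos_ha <= 1.0:
            raise ValueError("no sunrise/sunset at this latitude and date")
        ha = math.degrees(math.acos(cos_ha))
        if rising:
            minutes = 720.0 - 4.0 * (lon + ha) - eqtime
        else:
            minutes = 720.0 - 4.0 * (lon - ha) - eqtime
    return minutes


def noaa_sun_events(lat: float, lon: float, day: Date) -> tuple[datetime, datetime]:
    """(sunset on `day`, sunrise on the following day), both UTC."""
    sunset_min = _event_minutes(lat, lon, day, rising=False)
    sunset = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
        minutes=sunset_min
    )
    nxt = day + timedelta(days=1)
    sunrise_min = _event_minutes(lat, lon, nxt, rising=True)
    sunrise = datetime(nxt.year, nxt.month, nxt.day, tzinfo=timezone.utc) + timedelta(
        minutes=sunrise_min
    )
    return sunset, sunrise


def law_of_cosines_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance by the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    central = math.acos(
        min(
            1.0,
            max(
                -1.0,
                math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl),
            ),
        )
    )
    return EARTH_RADIUS_KM * central
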