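"""Low-precision solar and lunar positions.

Standard low-precision astronomical formulas (Meeus-class truncated
series): geocentric right ascension/declination of the sun and moon,
local sidereal time, altitudes, and the illuminated fraction of the
lunar disc.  Accuracy is on the order of a minute for rise/set events
and ~0.01 for the illuminated fraction — ample for classifying nights
into 15%/85% phase bins and for minute-grid horizon tests.

All angles are radians internally; public helpers accept and return
degrees/UTC datetimes.  Positions are geocentric; rise/set thresholds
absorb refraction and lunar parallax (see SUN_HORIZON_DEG and
MOON_HORIZON_DEG).
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np

__all__ = [
    "days_since_j2000",
    "sun_radec",
    "moon_radec_dist",
    "sun_altitude_deg",
    "moon_altitude_deg",
    "moon_illuminated_fraction",
    "SUN_HORIZON_DEG",
    "MOON_HORIZON_DEG",
    "SYNODIC_MONTH_DAYS",
]

_J2000 = datetime(2000, 1, 1, 12, tzinfo=timezone.utc)
_OBLIQUITY = math.radians(23.4397)
_SUN_DISTANCE_KM = 149_598_000.0

#: Geometric solar altitude at rise/set: refraction (34') + semidiameter (16').
SUN_HORIZON_DEG = -0.833
#: Geocentric lunar altitude at rise/set: refraction + semidiameter − parallax.
MOON_HORIZON_DEG = 0.125

#: Mean synodic month (days between successive full moons).
SYNODIC_MONTH_DAYS = 29.530588853


def days_since_j2000(when: datetime) -> float:
    """Fractional days since the J2000.0 epoch (2000-01-01 12:00 UTC)."""
    if when.tzinfo is None:
        when = when.replace(tzinfo=timezone.utc)
    return (when - _J2000).total_seconds() / 86400.0


def _ecliptic_to_equatorial(lon, lat):
    sin_lon, cos_lon = np.sin(lon), np.cos(lon)
    sin_e, cos_e = math.sin(_OBLIQUITY), math.cos(_OBLIQUITY)
    dec = np.arcsin(np.sin(lat) * cos_e + np.cos(lat) * sin_e * sin_lon)
    ra = np.arctan2(sin_lon * cos_e - np.tan(lat) * sin_e, cos_lon)
    return ra, dec


def sun_radec(d):
    """Solar geocentric (RA, dec) in radians at `d` days since J2000."""
    M = np.radians(357.5291 + 0.98560028 * d)  # mean anomaly
    C = np.radians(1.9148 * np.sin(M) + 0.02 * np.sin(2 * M) + 0.0003 * np.sin(3 * M))
    lon = M + C + math.radians(102.9372) + math.pi  # ecliptic longitude
    return _ecliptic_to_equatorial(lon, np.zeros_like(np.asarray(d, dtype=float)))


def moon_radec_dist(d):
    """Lunar geocentric (RA, dec, distance km) at `d` days since J2000."""
    L = np.radians(218.316 + 13.176396 * d)  # mean longitude
    M = np.radians(134.963 + 13.064993 * d)  # mean anomaly
    F = np.radians(93.272 + 13.229350 * d)  # argument of latitude
    lon = L + np.radians(6.289) * np.sin(M)
    lat = np.radians(5.128) * np.sin(F)
    dist = 385_001.0 - 20_905.0 * np.cos(M)
    ra, dec = _ecliptic_to_equatorial(lon, lat)
    return ra, dec, dist


def _sidereal_time(d, lon_east_rad):
    return np.radians(280.16 + 360.9856235 * np.asarray(d, dtype=float)) + lon_east_rad


def _altitude(ra, dec, d, lat_rad, lon_east_rad):
    H = _sidereal_time(d, lon_east_rad) - ra
    return np.arcsin(
        np.sin(lat_rad) * np.sin(dec) + np.cos(lat_rad) * np.cos(dec) * np.cos(H)
    )


def sun_altitude_deg(d, latitude: float, longitude: float):
    """Geometric solar altitude (degrees) for days-since-J2000 `d` (scalar or array)."""
    ra, dec = sun_radec(d)
    return np.degrees(
        _altitude(ra, dec, d, math.radians(latitude), math.radians(longitude))
    )


def moon_altitude_deg(d, latitude: float, longitude: float):
    """Geocentric lunar altitude (degrees) for days-since-J2000 `d`."""
    ra, dec, _ = moon_radec_dist(d)
    return np.degrees(
        _altitude(ra, dec, d, math.radians(latitude), math.radians(longitude))
    )


def moon_illuminated_fraction(d):
    """Illuminated fraction of the lunar disc in [0, 1].

    0 at new moon, 1 at full moon, near-sinusoidal with the synodic
    period.  Computed from the geocentric elongation and the phase
    angle of the moon (sun–moon–earth triangle).
    """
    sra, sdec = sun_radec(d)
    mra, mdec, mdist = moon_radec_dist(d)
    cos_phi = np.sin(sdec) * np.sin(mdec) + np.cos(sdec) * np.cos(mdec) * np.cos(
        sra - mra
    )
    phi = np.arccos(np.clip(cos_phi, -1.0, 1.0))  # geocentric elongation
    inc = np.arctan2(
        _SUN_DISTANCE_KM * np.sin(phi), mdist - _SUN_DISTANCE_KM * np.cos(phi)
    )  # phase angle
    return (1.0 + np.cos(inc)) / 2.0
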