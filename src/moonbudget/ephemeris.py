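"""Per-night solar/lunar context for a field site.

Everything downstream of the raw logger data is organised around the
*night*: anchored to the evening's calendar date, running from sunset
to the next sunrise, with an analysis window trimmed to [sunset − 1 h,
sunrise − 2 h] to match when nocturnal birds can actually be observed.
This module computes, for any site and date: sunset/sunrise, the times
the moon rises and sets within the night, the illuminated fraction of
the moon, a three-way phase class (new < 15%, full > 85% illuminated,
intermediate otherwise), the number of night hours with the moon above
the horizon, and the position of a date within the ~29.53-day synodic
cycle.

Event times are found by scanning geometric altitudes on a one-minute
grid and interpolating the horizon crossing, which keeps the whole
module dependent only on the closed-form positions in
:mod:`moonbudget.astro`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, time, timedelta, timezone
from typing import Iterable

import numpy as np
import pandas as pd

from . import astro

__all__ = [
    "Site",
    "NightContext",
    "NoSunEventError",
    "DONANA",
    "NEW_MOON_MAX_FRACTION",
    "FULL_MOON_MIN_FRACTION",
    "sun_events",
    "moon_illumination",
    "classify_moon_phase",
    "moonlight_hours",
    "lunar_cycle_day",
    "night_context",
    "nights_table",
    "full_moon_dates",
]

#: Illuminated-fraction thresholds for the three-way phase classification.
NEW_MOON_MAX_FRACTION = 0.15
FULL_MOON_MIN_FRACTION = 0.85

#: Analysis-window trims relative to sunset / next sunrise (hours).
WINDOW_START_TRIM_H = -1.0
WINDOW_END_TRIM_H = -2.0


class NoSunEventError(ValueError):
    """The sun does not cross the horizon on this date (polar day/night)."""


@dataclass(frozen=True)
class Site:
    """A study site. Latitude +N, longitude +E, both in decimal degrees."""

    latitude: float
    longitude: float
    label: str = ""

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


#: The Doñana National Park study site (37°7'N, 6°33'W).
DONANA = Site(latitude=37.117, longitude=-6.55, label="Donana")


@dataclass(frozen=True)
class NightContext:
    """Solar/lunar context of one night, anchored to the evening's date."""

    date: Date
    sunset: datetime
    sunrise_next: datetime
    moonrise: datetime | None
    moonset: datetime | None
    illuminated_fraction: float
    phase_class: str
    moonlight_hours: float
    window_start: datetime = field(default=None)  # type: ignore[assignment]
    window_end: datetime = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.sunset >= self.sunrise_next:
            raise ValueError("sunset must precede the next sunrise")
        night_h = (self.sunrise_next - self.sunset).total_seconds() / 3600.0
        if not 0.0 <= self.moonlight_hours <= night_h + 1e-9:
            raise ValueError("moonlight_hours outside [0, night duration]")
        if self.window_start is None:
            object.__setattr__(
                self, "window_start", self.sunset + timedelta(hours=WINDOW_START_TRIM_H)
            )
        if self.window_end is None:
            object.__setattr__(
                self, "window_end", self.sunrise_next + timedelta(hours=WINDOW_END_TRIM_H)
            )

    @property
    def night_hours(self) -> float:
        return (self.sunrise_next - self.sunset).total_seconds() / 3600.0

    def contains(self, when: datetime) -> bool:
        """True if `when` falls within the sunset→sunrise night."""
        return self.sunset <= _as_utc(when) < self.sunrise_next


def _as_utc(when: datetime) -> datetime:
    if when.tzinfo is None:
        return when.replace(tzinfo=timezone.utc)
    return when.astimezone(timezone.utc)


def _interp_crossing(
    start: datetime, alt: np.ndarray, i: int, threshold: float
) -> datetime:
    """Linear-interpolated instant where alt crosses `threshold` in [i, i+1]."""
    a0, a1 = alt[i], alt[i + 1]
    frac = 0.0 if a1 == a0 else (threshold - a0) / (a1 - a0)
    return start + timedelta(minutes=i + float(np.clip(frac, 0.0, 1.0)))


def sun_events(site: Site, date: Date) -> tuple[datetime, datetime]:
    """Sunset on `date` and the following sunrise, both UTC.

    The search spans one solar day starting at local solar noon, so the
    returned pair always brackets the night anchored to `date`.

    Raises
    ------
    NoSunEventError
        If the sun never crosses the horizon (polar day or night).
    """
    solar_noon = datetime.combine(date, time(12, 0), tzinfo=timezone.utc) - timedelta(
        hours=site.longitude / 15.0
    )
    d0 = astro.days_since_j2000(solar_noon)
    d = d0 + np.arange(24 * 60 + 2) / 1440.0
    alt = astro.sun_altitude_deg(d, site.latitude, site.longitude)
    above = alt > astro.SUN_HORIZON_DEG
    if above.all():
        raise NoSunEventError(f"polar day at {site.latitude:.2f}° on {date}")
    if not above.any():
        raise NoSunEventError(f"polar night at {site.latitude:.2f}° on {date}")
    down = np.nonzero(above[:-1] & ~above[1:])[0]
    if down.size == 0:
        raise NoSunEventError(f"no sunset found at {site.latitude:.2f}° on {date}")
    i_set = int(down[0])
    up = np.nonzero(~above[:-1] & above[1:])[0]
    up = up[up >= i_set]
    if up.size == 0:
        raise NoSunEventError(f"no sunrise found at {site.latitude:.2f}° on {date}")
    i_rise = int(up[0])
    sunset = _interp_crossing(solar_noon, alt, i_set, astro.SUN_HORIZON_DEG)
    sunrise = _interp_crossing(solar_noon, alt, i_rise, astro.SUN_HORIZON_DEG)
    return sunset, sunrise


def moon_illumination(when: datetime) -> float:
    """Illuminated fraction of the moon's disc at a UTC instant, in [0, 1]."""
    return float(astro.moon_illuminated_fraction(astro.days_since_j2000(_as_utc(when))))


def classify_moon_phase(
    illuminated_fraction: float,
    new_max: float = NEW_MOON_MAX_FRACTION,
    full_min: float = FULL_MOON_MIN_FRACTION,
) -> str:
    """Classify a night by illuminated fraction: 'new', 'full' or 'intermediate'."""
    if not 0.0 <= illuminated_fraction <= 1.0:
        raise ValueError(f"illuminated fraction outside [0, 1]: {illuminated_fraction}")
    if illuminated_fraction < new_max:
        return "new"
    if illuminated_fraction > full_min:
        return "full"
    return "intermediate"


def _night_moon(
    site: Site, sunset: datetime, sunrise: datetime
) -> tuple[float, datetime | None, datetime | None]:
    """(moonlight hours, moonrise, moonset) within [sunset, sunrise].

    Rise/set are the horizon crossings inside the night window; a moon
    already up at sunset has no `moonrise`, one still up at sunrise has
    no `moonset`.
    """
    n = int((sunrise - sunset).total_seconds() // 60) + 1
    d = astro.days_since_j2000(sunset) + np.arange(n) / 1440.0
    alt = astro.moon_altitude_deg(d, site.latitude, site.longitude)
    above = alt > astro.MOON_HORIZON_DEG
    night_h = (sunrise - sunset).total_seconds() / 3600.0
    hours = float(above.mean() * night_h)
    rise = set_ = None
    ups = np.nonzero(~above[:-1] & above[1:])[0]
    downs = np.nonzero(above[:-1] & ~above[1:])[0]
    if ups.size:
        rise = _interp_crossing(sunset, alt, int(ups[0]), astro.MOON_HORIZON_DEG)
    if downs.size:
        set_ = _interp_crossing(sunset, alt, int(downs[0]), astro.MOON_HORIZON_DEG)
    return hours, rise, set_


def moonlight_hours(site: Site, date: Date) -> float:
    """Hours between sunset and the next sunrise with the moon above the horizon."""
    sunset, sunrise = sun_events(site, date)
    hours, _, _ = _night_moon(site, sunset, sunrise)
    return hours


def lunar_cycle_day(date: Date | datetime, reference_full_moon: Date | datetime) -> float:
    """Days into the synodic cycle: (date − reference full moon) mod 29.53."""
    if isinstance(date, datetime):
        date = _as_utc(date)
    else:
        date = datetime.combine(date, time(0, 0), tzinfo=timezone.utc)
    if isinstance(reference_full_moon, datetime):
        ref = _as_utc(reference_full_moon)
    else:
        ref = datetime.combine(reference_full_moon, time(0, 0), tzinfo=timezone.utc)
    delta = (date - ref).total_seconds() / 86400.0
    return float(delta % astro.SYNODIC_MONTH_DAYS)


def night_context(
    site: Site,
    date: Date,
    new_max: float = NEW_MOON_MAX_FRACTION,
    full_min: float = FULL_MOON_MIN_FRACTION,
    illum_time: datetime | None = None,
) -> NightContext:
    """Full solar/lunar context of the night anchored to `date`.

    The illuminated fraction is evaluated at local solar midnight (the
    midpoint of sunset and sunrise) unless `illum_time` is given.
    """
    sunset, sunrise = sun_events(site, date)
    hours, rise, set_ = _night_moon(site, sunset, sunrise)
    when = illum_time if illum_time is not None else sunset + (sunrise - sunset) / 2
    frac = moon_illumination(when)
    return NightContext(
        date=date,
        sunset=sunset,
        sunrise_next=sunrise,
        moonrise=rise,
        moonset=set_,
        illuminated_fraction=frac,
        phase_class=classify_moon_phase(frac, new_max, full_min),
        moonlight_hours=hours,
    )


def nights_table(site: Site, dates: Iterable[Date]) -> pd.DataFrame:
    """Per-night context table: one row per date.

    Columns: date, sunset_utc, sunrise_utc, moonrise_utc, moonset_utc,
    illum_frac, phase_class, moonlight_h.
    """
    rows = []
    for date in dates:
        ctx = night_context(site, date)
        rows.append(
            {
                "date": ctx.date.isoformat(),
                "sunset_utc": ctx.sunset.isoformat(),
                "sunrise_utc": ctx.sunrise_next.isoformat(),
                "moonrise_utc": ctx.moonrise.isoformat() if ctx.moonrise else "",
                "moonset_utc": ctx.moonset.isoformat() if ctx.moonset else "",
                "illum_frac": round(ctx.illuminated_fraction, 4),
                "phase_class": ctx.phase_class,
                "moonlight_h": round(ctx.moonlight_hours, 3),
            }
        )
    return pd.DataFrame(rows)


def full_moon_dates(start: Date, end: Date) -> list[datetime]:
    """UTC instants of maximal illumination (full moons) in [start, end].

    Scans the illuminated fraction hourly and refines each local
    maximum on a minute grid; successive entries are ~29.53 days apart.
    """
    t0 = datetime.combine(start, time(0, 0), tzinfo=timezone.utc)
    t1 = datetime.combine(end, time(0, 0), tzinfo=timezone.utc)
    n = int((t1 - t0).total_seconds() // 3600) + 1
    d = astro.days_since_j2000(t0) + np.arange(n) / 24.0
    frac = astro.moon_illuminated_fraction(d)
    peaks = [
        i
        for i in range(1, n - 1)
        if frac[i] >= frac[i - 1] and frac[i] >= frac[i + 1] and frac[i] > 0.95
    ]
    out = []
    for i in peaks:
        dd = d[i] + (np.arange(-60, 61) / 1440.0)
        ff = astro.moon_illuminated_fraction(dd)
        j = int(np.argmax(ff))
        out.append(t0 + timedelta(days=float(dd[j] - d[0])))
    return out
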