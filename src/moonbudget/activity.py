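"""Flight-activity classification and movement segmentation.

Multisensor data loggers sample z-axis acceleration in short bursts
(10 values over 100 ms); wingbeats leave large demeaned excursions, so
a burst is classified as flight when at least three demeaned samples
exceed |g/3|.  Bursts aggregate to hourly foraging fractions (tf, the
model's foraging-time input), actogram-style per-5-min activity values
feed migratory-flight segmentation, and GPS fixes yield great-circle
daily displacements with a 10-km stationary/movement rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccelBurst",
    "MigrationSegment",
    "GpsFix",
    "FLIGHT_THRESHOLD_G",
    "FLIGHT_MIN_EXCEEDANCES",
    "MOVEMENT_THRESHOLD_KM",
    "CORE_ACTIVITY_THRESHOLD",
    "classify_burst",
    "hourly_foraging_fraction",
    "activity_values_5min",
    "detect_migratory_flights",
    "nightly_flight_flag",
    "haversine_km",
    "daily_displacement",
]

#: Demeaned acceleration (g) a sample must exceed to count toward flight.
FLIGHT_THRESHOLD_G = 1.0 / 3.0
#: Number of exceeding samples required to call a burst flight.
FLIGHT_MIN_EXCEEDANCES = 3
#: Daily displacement (km) above which a bird is classed as moving.
MOVEMENT_THRESHOLD_KM = 10.0
#: Core flight period threshold on 5-min activity values, per tag version.
CORE_ACTIVITY_THRESHOLD = {"2016": 6, "2017": 6, "2018": 3}

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class AccelBurst:
    """One acceleration burst: a timestamp and 5–10 z-axis samples in g."""

    bird_id: str
    timestamp: datetime
    samples: tuple[float, ...]

    def __post_init__(self):
        if len(self.samples) < 5:
            raise ValueError("burst needs at least 5 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("burst samples must be finite")


@dataclass(frozen=True)
class MigrationSegment:
    bird_id: str
    start: datetime
    end: datetime

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must follow start")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def overlap_hours(self, start: datetime, end: datetime) -> float:
        lo = max(self.start, start)
        hi = min(self.end, end)
        return max(0.0, (hi - lo).total_seconds() / 3600.0)


@dataclass(frozen=True)
class GpsFix:
    bird_id: str
    timestamp: datetime
    latitude: float
    longitude: float

    def __post_init__(self):
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
            raise ValueError("invalid coordinates")


def classify_burst(samples: Sequence[float] | AccelBurst) -> bool:
    """Flight/non-flight call for one burst.

    The burst mean is subtracted from every sample (removing static
    gravity along whatever the tag's resting orientation is); the burst
    is flight if ≥3 demeaned samples exceed |g/3|.  The rule is
    therefore invariant to any constant offset.
    """
    if isinstance(samples, AccelBurst):
        samples = samples.samples
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("empty burst")
    demeaned = arr - arr.mean()
    return int(np.sum(np.abs(demeaned) > FLIGHT_THRESHOLD_G)) >= FLIGHT_MIN_EXCEEDANCES


def _floor_hour(ts: datetime) -> datetime:
    return ts.replace(minute=0, second=0, microsecond=0)


def hourly_foraging_fraction(
    bursts: Iterable[AccelBurst],
    migration_segments: Sequence[MigrationSegment] = (),
) -> pd.DataFrame:
    """Aggregate bursts to hourly foraging (tf) and migration (tmr) fractions.

    Activity outside migratory-flight segments counts as potential
    foraging: tf = flight-positive bursts / total bursts in the clock
    hour (UTC).  An hour lying fully inside a migration segment gets
    tf = 0 and tmr = 1; partial overlap splits pro rata.  Hours with no
    bursts are absent from the result (missing, not zero).

    Returns a DataFrame with columns bird_id, hour_start, n_samples,
    n_flight, tf, tmr.
    """
    rows: dict[tuple[str, datetime], list[int]] = {}
    seen: set[tuple[str, datetime]] = set()
    for b in bursts:
        key = (b.bird_id, b.timestamp)
        if key in seen:
            raise ValueError(f"duplicate burst timestamp {b.timestamp} for {b.bird_id}")
        seen.add(key)
        hkey = (b.bird_id, _floor_hour(b.timestamp))
        cell = rows.setdefault(hkey, [0, 0])
        cell[0] += 1
        cell[1] += int(classify_burst(b))
    out = []
    for (bird, hour), (n, nf) in sorted(rows.items()):
        hour_end = hour + timedelta(hours=1)
        mig_h = sum(
            s.overlap_hours(hour, hour_end)
            for s in migration_segments
            if s.bird_id == bird
        )
        tmr = min(1.0, mig_h)
        tf = (nf / n) * (1.0 - tmr)
        out.append(
            {
                "bird_id": bird,
                "hour_start": hour,
                "n_samples": n,
                "n_flight": nf,
                "tf": tf,
                "tmr": tmr,
            }
        )
    return pd.DataFrame(
        out, columns=["bird_id", "hour_start", "n_samples", "n_flight", "tf", "tmr"]
    )


def activity_values_5min(bursts: Iterable[AccelBurst]) -> pd.DataFrame:
    """Per-5-min activity values: count of flight-positive bursts.

    On the 2016–17 schedule (10 bursts/5 min) values run 0–10, on the
    2018 schedule (5 bursts/5 min) 0–5.  Columns: bird_id,
    interval_start, value, n_bursts.
    """
    rows: dict[tuple[str, datetime], list[int]] = {}
    for b in bursts:
        ts = b.timestamp
        interval = ts.replace(minute=(ts.minute // 5) * 5, second=0, microsecond=0)
        cell = rows.setdefault((b.bird_id, interval), [0, 0])
        cell[0] += 1
        cell[1] += int(classify_burst(b))
    out = [
        {"bird_id": bird, "interval_start": t, "value": v, "n_bursts": n}
        for (bird, t), (n, v) in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["bird_id", "interval_start", "value", "n_bursts"])


def detect_migratory_flights(
    values_5min: pd.DataFrame, tag_version: str
) -> list[MigrationSegment]:
    """Segment sustained migratory flight from per-5-min activity values.

    Core flight hours are clock hours of generally high activity:
    every 5-min value positive and the hourly mean value at or above
    the tag-version threshold (≥6 for 2016–17 tags on the 0–10 scale,
    ≥3 for 2018 tags on the 0–5 scale).  Maximal runs of core hours
    form core periods; each end is then extended by 5 min for every
    at-threshold interval in the hour immediately before (after) the
    core period.  Overlapping segments are merged.
    """
    if tag_version not in CORE_ACTIVITY_THRESHOLD:
        raise ValueError(f"unknown tag version: {tag_version!r}")
    thr = CORE_ACTIVITY_THRESHOLD[tag_version]
    segments: list[MigrationSegment] = []
    for bird, df in values_5min.groupby("bird_id"):
        df = df.sort_values("interval_start")
        by_hour: dict[datetime, list[int]] = {}
        for ts, val in zip(df["interval_start"], df["value"]):
            by_hour.setdefault(_floor_hour(ts), []).append(int(val))
        hours = sorted(by_hour)

        def is_core(h: datetime) -> bool:
            vals = by_hour[h]
            return len(vals) > 0 and min(vals) > 0 and float(np.mean(vals)) >= thr

        def n_qualifying(h: datetime) -> int:
            return sum(v >= thr for v in by_hour.get(h, []))

        i = 0
        while i < len(hours):
            if not is_core(hours[i]):
                i += 1
                continue
            j = i
            while (
                j + 1 < len(hours)
                and hours[j + 1] == hours[j] + timedelta(hours=1)
                and is_core(hours[j + 1])
            ):
                j += 1
            start = hours[i] - timedelta(
                minutes=5 * n_qualifying(hours[i] - timedelta(hours=1))
            )
            end = (
                hours[j]
                + timedelta(hours=1)
                + timedelta(minutes=5 * n_qualifying(hours[j] + timedelta(hours=1)))
            )
            segments.append(MigrationSegment(bird_id=str(bird), start=start, end=end))
            i = j + 1
    return _merge_segments(segments)


def _merge_segments(segments: list[MigrationSegment]) -> list[MigrationSegment]:
    out: list[MigrationSegment] = []
    for seg in sorted(segments, key=lambda s: (s.bird_id, s.start)):
        if out and out[-1].bird_id == seg.bird_id and seg.start <= out[-1].end:
            prev = out.pop()
            seg = MigrationSegment(
                bird_id=seg.bird_id, start=prev.start, end=max(prev.end, seg.end)
            )
        out.append(seg)
    return out


def nightly_flight_flag(
    segments: Sequence[MigrationSegment],
    night_start: datetime,
    night_end: datetime,
    gps_displacement_km: float | None = None,
) -> bool:
    """True if the night holds ≥1 h of migratory flight or a >10 km GPS move."""
    mdl_hours = sum(s.overlap_hours(night_start, night_end) for s in segments)
    if mdl_hours >= 1.0:
        return True
    if gps_displacement_km is not None and gps_displacement_km > MOVEMENT_THRESHOLD_KM:
        return True
    return False


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def daily_displacement(fixes: Sequence[GpsFix]) -> pd.DataFrame:
    """Daily translocation distances from one representative fix per day.

    For each bird the fix closest to local solar midnight of each
    calendar day is kept (the birds move at night); consecutive daily
    fixes give the great-circle displacement and a stationary/movement
    class at the 10-km threshold.  Columns: bird_id, date, km, moving.
    Fewer than two daily fixes yield an empty result.
    """
    rows = []
    by_bird: dict[str, list[GpsFix]] = {}
    for f in fixes:
        by_bird.setdefault(f.bird_id, []).append(f)
    for bird, fl in by_bird.items():
        fl = sorted(fl, key=lambda f: f.timestamp)
        daily: dict = {}
        for f in fl:
            day = f.timestamp.date()  # UTC date keys the day stably
            # representative fix: closest to local solar midnight
            # (00:00 − lon/15 h UTC) of that date
            midnight = datetime.combine(day, datetime.min.time(), timezone.utc) - timedelta(
                hours=f.longitude / 15.0
            )
            dist = abs((f.timestamp - midnight).total_seconds())
            if day not in daily or dist < daily[day][0]:
                daily[day] = (dist, f)
        days = sorted(daily)
        for d0, d1 in zip(days[:-1], days[1:]):
            f0, f1 = daily[d0][1], daily[d1][1]
            km = haversine_km(f0.latitude, f0.longitude, f1.latitude, f1.longitude)
            rows.append(
                {
                    "bird_id": bird,
                    "date": d1,
                    "km": km,
                    "moving": km > MOVEMENT_THRESHOLD_KM,
                }
            )
    return pd.DataFrame(rows, columns=["bird_id", "date", "km", "moving"])
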