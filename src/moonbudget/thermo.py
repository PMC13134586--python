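"""Heterothermy and torpor from hourly skin-temperature series.

Dorsally mounted skin-temperature sensors are solar-heated by day, so
all analysis is restricted to nighttime records; migratory-flight
hours are excluded too (altitude-driven ambient cooling contaminates
the sensor).  Two quantities are derived per bird:

* the heterothermy index, HI = sqrt( Σ (T_mod − T_i)² / (n − 1) ), the
  root-mean-square deviation of nightly skin temperature from the
  bird's modal (typical) skin temperature; and
* torpor events: maximal runs of inactive nocturnal hours whose skin
  temperature falls more than k·SD (k = 2 by default, 3 for the
  stricter sensitivity setting) below the bird's reference level.

The reference mean/SD are computed on *active* nighttime records (the
bird's normothermic operating range); the modal temperature comes from
a 0.5 °C-binned histogram of nighttime records.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "ThermoSummary",
    "TorporEvent",
    "skin_temp_summary",
    "modal_temperature",
    "heterothermy_index",
    "detect_torpor",
    "torpor_onset_lag",
    "torpor_fraction",
]

#: Histogram bin width (°C) for the modal skin temperature.
MODE_BIN_C = 0.5


@dataclass(frozen=True)
class ThermoSummary:
    """Per-bird reference skin-temperature statistics."""

    bird_id: str
    Tsk_mode: float
    Tsk_mean: float
    Tsk_sd: float
    n: int


@dataclass(frozen=True)
class TorporEvent:
    bird_id: str
    onset: datetime
    end: datetime
    min_Tsk: float
    threshold_used: float

    def __post_init__(self):
        if self.min_Tsk >= self.threshold_used:
            raise ValueError("event minimum must fall below the threshold")


def modal_temperature(tsk, bin_width: float = MODE_BIN_C) -> float:
    """Modal temperature: mean of the records in the fullest histogram bin.

    Binning at 0.5 °C smooths sensor noise; averaging within the modal
    bin keeps the mode exact for (near-)constant series.  Ties go to
    the lowest bin.
    """
    arr = np.asarray(tsk, dtype=float)
    if arr.size == 0:
        raise ValueError("no temperature records")
    lo = np.floor(arr.min() / bin_width) * bin_width
    hi = np.ceil(arr.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    i = int(np.argmax(counts))
    in_bin = arr[(arr >= edges[i]) & (arr < edges[i + 1])]
    if in_bin.size == 0:  # modal value sits on the last closed edge
        in_bin = arr[arr == edges[i + 1]]
    return float(in_bin.mean())


def skin_temp_summary(series: pd.DataFrame, min_n: int = 50) -> ThermoSummary:
    """Reference statistics for one bird's nighttime skin temperatures.

    Mean and SD are computed over *active* nighttime non-migration
    records; the mode over all nighttime non-migration records.

    Parameters
    ----------
    series : DataFrame with columns bird_id, hour_start, tsk, active,
        is_night and optionally in_migration.
    min_n : minimum number of active nighttime records required.
    """
    night = series[series["is_night"]]
    if "in_migration" in night:
        night = night[~night["in_migration"].astype(bool)]
    active = night[night["active"].astype(bool)]
    if len(active) < min_n:
        raise ValueError(
            f"only {len(active)} active nighttime records (need ≥ {min_n})"
        )
    bird = str(series["bird_id"].iloc[0]) if len(series) else ""
    return ThermoSummary(
        bird_id=bird,
        Tsk_mode=modal_temperature(night["tsk"]),
        Tsk_mean=float(active["tsk"].mean()),
        Tsk_sd=float(active["tsk"].std(ddof=1)),
        n=len(active),
    )


def heterothermy_index(tsk, mode: float | None = None) -> float:
    """HI (°C): RMS deviation from the modal temperature, denominator n−1.

    `mode` defaults to the binned-histogram mode of the records
    themselves (per-day use passes the bird's long-run mode instead).
    Needs at least two records.
    """
    arr = np.asarray(tsk, dtype=float)
    if arr.size < 2:
        raise ValueError("HI needs at least 2 records")
    if mode is None:
        mode = modal_temperature(arr)
    return float(np.sqrt(np.sum((mode - arr) ** 2) / (arr.size - 1)))


def detect_torpor(
    series: pd.DataFrame,
    summary: ThermoSummary,
    k_sd: float = 2.0,
    anchor: str = "mean",
    min_duration_h: int = 1,
) -> list[TorporEvent]:
    """Scan inactive nocturnal hours for sub-threshold skin temperatures.

    The torpor threshold is (mean − k_sd·SD) of the bird's reference
    statistics (`anchor="mode"` substitutes the modal temperature for
    the mean).  Events are maximal runs of consecutive inactive,
    nocturnal, non-migratory hours below threshold, at least
    `min_duration_h` long.

    Parameters
    ----------
    series : DataFrame with columns hour_start, tsk, active, is_night
        and optionally in_migration; one bird.
    k_sd : 2 (default) or 3 for the conservative sensitivity setting.
    """
    if summary is None:
        raise ValueError("per-bird reference summary required")
    centre = summary.Tsk_mean if anchor == "mean" else summary.Tsk_mode
    threshold = centre - k_sd * summary.Tsk_sd
    df = series.sort_values("hour_start").reset_index(drop=True)
    mig = (
        df["in_migration"].astype(bool)
        if "in_migration" in df
        else pd.Series(False, index=df.index)
    )
    eligible = (
        df["is_night"].astype(bool)
        & ~df["active"].astype(bool)
        & ~mig
        & (df["tsk"] < threshold)
    ).to_numpy()
    hours = pd.to_datetime(df["hour_start"]).to_list()
    events: list[TorporEvent] = []
    i = 0
    n = len(df)
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and eligible[j + 1]
            and hours[j + 1] - hours[j] == timedelta(hours=1)
        ):
            j += 1
        if j - i + 1 >= min_duration_h:
            events.append(
                TorporEvent(
                    bird_id=summary.bird_id,
                    onset=hours[i],
                    end=hours[j] + timedelta(hours=1),
                    min_Tsk=float(df["tsk"].iloc[i : j + 1].min()),
                    threshold_used=float(threshold),
                )
            )
        i = j + 1
    return events


def torpor_onset_lag(events, nights) -> pd.DataFrame:
    """Signed lag (h) between torpor onset and the night's moonset.

    Positive lags mean the bird entered torpor after the moon set.
    Nights without a nocturnal moonset are excluded.

    Parameters
    ----------
    events : iterable of TorporEvent.
    nights : iterable of NightContext covering the event nights.
    """
    by_night = {}
    for ctx in nights:
        by_night[(ctx.sunset, ctx.sunrise_next)] = ctx
    rows = []
    for ev in events:
        for (lo, hi), ctx in by_night.items():
            if lo <= ev.onset < hi:
                if ctx.moonset is None:
                    break
                lag = (ev.onset - ctx.moonset).total_seconds() / 3600.0
                rows.append(
                    {
                        "bird_id": ev.bird_id,
                        "night_date": ctx.date,
                        "onset": ev.onset,
                        "moonset": ctx.moonset,
                        "lag_h": lag,
                    }
                )
                break
    return pd.DataFrame(rows, columns=["bird_id", "night_date", "onset", "moonset", "lag_h"])


def torpor_fraction(events_by_bird: dict, dates, birds_with_data) -> pd.Series:
    """Per-date fraction of tracked birds with a torpor event that night.

    Parameters
    ----------
    events_by_bird : {bird_id: list of TorporEvent}.
    dates : iterable of calendar dates (night anchors).
    birds_with_data : {date: set of bird_ids with usable data}, or a
        fixed collection applied to every date.

    Nights are matched on the onset's anchor date (the evening date:
    onsets after midnight belong to the previous calendar date).
    """
    out = {}
    for d in dates:
        if isinstance(birds_with_data, dict):
            tracked = set(birds_with_data.get(d, set()))
        else:
            tracked = set(birds_with_data)
        if not tracked:
            out[d] = np.nan
            continue
        with_event = set()
        for bird, evs in events_by_bird.items():
            if bird not in tracked:
                continue
            for ev in evs:
                anchor = ev.onset.date()
                if ev.onset.hour < 12:
                    anchor = anchor - timedelta(days=1)
                if anchor == d:
                    with_event.add(bird)
                    break
        out[d] = len(with_event) / len(tracked)
    return pd.Series(out, name="torpor_fraction")
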