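"""Seeded synthetic biologging datasets with the field data's structure.

The generator emulates the statistical structure the analysis assumes
so every pipeline stage can be exercised without any field data:

* dusk/dawn activity peaks with moonlight-gated nocturnal activity
  (nocturnal foraging probability stays high through moonlit nights,
  collapses on dark nights, with a reduced dawn bout after dark
  nights);
* skin temperature: euthermic ~38 °C baseline with sensor noise, and
  torpor bouts on energy-deficit nights starting a configurable lag
  (~1 h) after moonset, trough 32–34 °C;
* capture tables whose body masses carry a lunar sinusoid (peak a
  configurable number of days after full moon), a fuel-deposition
  ramp after a configurable onset, and gizzard-content mass
  consistent with the sampled gizzard score (declining through dark
  nights, intermediate plateau on moonlit nights);
* GPS tracks with sub-10-km stationary jitter and migration nights
  displacing 150–400 km, clustered at a fixed lag after full moon.

Every generator draws from its own deterministic stream of the config
seed and emits machine-readable ground truth as separate sidecar
tables, so downstream recovery tests cannot read the answers out of
the data files.  Real lunar geometry for the simulated year comes
from :mod:`moonbudget.ephemeris`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import ephemeris
from .ephemeris import DONANA, NightContext, Site

__all__ = [
    "SimConfig",
    "simulate_nights",
    "simulate_hourly_activity",
    "simulate_bursts",
    "simulate_temps",
    "simulate_captures",
    "simulate_gps_and_migration",
    "simulate_dataset",
]

# per-generator offsets added to the config seed → independent streams
_STREAM = {"activity": 1, "bursts": 2, "temps": 3, "captures": 4, "gps": 5}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study system (defaults = study conditions)."""

    seed: int = 0
    n_birds: int = 10
    start: Date = Date(2017, 5, 1)
    end: Date = Date(2017, 8, 31)
    site: Site = DONANA
    tag_version: str = "2016"

    # activity model: per-hour flight-burst probability by context.
    # Dark nights depress foraging success at dusk and especially dawn
    # (gizzard scores decline through dark nights; morning gizzards
    # only partially filled), which is what produces new-moon deficits.
    dusk_peak_p: float = 0.85
    dusk_peak_dark_p: float = 0.12
    dawn_peak_p: float = 0.75
    dawn_peak_dark_p: float = 0.05
    night_moonlit_p: float = 0.65  # stays >60% through moonlit nights
    night_dark_p: float = 0.005
    day_p: float = 0.005

    # torpor model
    torpor_onset_lag_h: float = 1.0
    torpor_deficit_p: float = 0.9  # probability on an energy-deficit night
    torpor_trough_c: tuple[float, float] = (32.0, 34.0)
    baseline_tsk_c: float = 38.0
    sensor_noise_sd_c: float = 0.3

    # body-mass / capture model
    lean_mass_g: float = 87.13
    lunar_amplitude_g: float = 1.2
    mass_peak_lag_days: float = 6.0
    fuel_onset: Date = Date(2017, 8, 1)
    true_fdr_g_day: float = 0.43
    mass_noise_sd_g: float = 0.4
    nightly_trap_p: float = 0.25
    Mgimax: float = 11.72

    # migration model
    migration_lag_days: float = 13.0
    n_flight_nights: int = 4
    flight_km_range: tuple[float, float] = (150.0, 400.0)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.seed * 16 + _STREAM[stream])


def simulate_nights(config: SimConfig) -> list[NightContext]:
    """Night contexts for every date of the simulated range."""
    n_days = (config.end - config.start).days + 1
    return [
        ephemeris.night_context(config.site, config.start + timedelta(days=i))
        for i in range(n_days)
    ]


def _hour_context(hour: datetime, night: NightContext, cfg: SimConfig):
    """Flight-burst probability for the clock hour starting at `hour`."""
    mid = hour + timedelta(minutes=30)
    if not (night.sunset - timedelta(hours=1) <= mid < night.sunrise_next + timedelta(hours=1)):
        return cfg.day_p
    dark = night.phase_class == "new"
    if abs((mid - night.sunset).total_seconds()) <= 3600:
        return cfg.dusk_peak_dark_p if dark else cfg.dusk_peak_p
    if abs((mid - night.sunrise_next).total_seconds()) <= 3600:
        return cfg.dawn_peak_dark_p if dark else cfg.dawn_peak_p
    if night.contains(mid):
        # moon up and bright → sustained foraging; otherwise near-quiescent
        moonlit = night.phase_class != "new" and night.moonlight_hours > 0
        if moonlit and _moon_up(mid, night):
            return cfg.night_moonlit_p * max(0.5, night.illuminated_fraction)
        return cfg.night_dark_p
    return cfg.day_p


def _moon_up(when: datetime, night: NightContext) -> bool:
    rise = night.moonrise or night.sunset
    set_ = night.moonset or night.sunrise_next
    if night.moonrise is None and night.moonset is None:
        return night.moonlight_hours > night.night_hours / 2
    return rise <= when < set_ if rise <= set_ else not (set_ <= when < rise)


def simulate_hourly_activity(
    config: SimConfig, nights: list[NightContext] | None = None
) -> pd.DataFrame:
    """Hourly foraging/migration fractions for every bird and hour.

    tf is a binomial draw (120 bursts/hour) around the context
    probability; migration nights (see the migration model) get tmr=1
    and tf=0 during the night hours.

    Returns bird_id, hour_start, tf, tmr.
    """
    nights = nights or simulate_nights(config)
    rng = config.rng("activity")
    mig = _migration_nights(config, nights)
    rows = []
    t0 = datetime.combine(config.start, datetime.min.time(), timezone.utc)
    n_hours = ((config.end - config.start).days + 1) * 24
    night_by_date = {n.date: n for n in nights}
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        mig_dates = mig.get(bird, set())
        for h in range(n_hours):
            hour = t0 + timedelta(hours=h)
            anchor = hour.date() if hour.hour >= 12 else hour.date() - timedelta(days=1)
            night = night_by_date.get(anchor)
            if night is None:
                continue
            if anchor in mig_dates and night.contains(hour + timedelta(minutes=30)):
                rows.append((bird, hour, 0.0, 1.0))
                continue
            p = _hour_context(hour, night, config)
            tf = rng.binomial(120, p) / 120.0
            rows.append((bird, hour, tf, 0.0))
    return pd.DataFrame(rows, columns=["bird_id", "hour_start", "tf", "tmr"])


def simulate_bursts(
    config: SimConfig, nights: list[NightContext] | None = None
) -> pd.DataFrame:
    """Burst-level accelerometer records on the tag sampling schedule.

    Every 5 min, 10 bursts (2016–17 tags) or 5 bursts (2018 tags) of
    10 z-axis samples each, 5 s apart.  A flight burst gets ≥3
    demeaned samples beyond |g/3| (alternating wingbeat signature); a
    rest burst gets small-amplitude noise.  Burst-level output grows
    quickly — use short date ranges.

    Returns bird_id, timestamp, s1..s10.
    """
    nights = nights or simulate_nights(config)
    rng = config.rng("bursts")
    per_interval = 10 if config.tag_version in ("2016", "2017") else 5
    night_by_date = {n.date: n for n in nights}
    rows = []
    t0 = datetime.combine(config.start, datetime.min.time(), timezone.utc)
    n_intervals = ((config.end - config.start).days + 1) * 24 * 12
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        for i in range(n_intervals):
            interval = t0 + timedelta(minutes=5 * i)
            anchor = (
                interval.date()
                if interval.hour >= 12
                else interval.date() - timedelta(days=1)
            )
            night = night_by_date.get(anchor)
            if night is None:
                continue
            p = _hour_context(interval.replace(minute=0), night, config)
            for k in range(per_interval):
                ts = interval + timedelta(seconds=5 * k)
                if rng.random() < p:
                    base = rng.uniform(-0.5, 0.5)
                    amp = rng.uniform(0.6, 1.5)
                    samples = base + amp * np.array(
                        [1, -1, 1, -1, 1, -1, 1, -1, 1, -1], dtype=float
                    ) * rng.uniform(0.7, 1.0, 10)
                else:
                    samples = rng.uniform(-0.5, 0.5) + rng.normal(0.0, 0.05, 10)
                rows.append((bird, ts, *np.round(samples, 4)))
    cols = ["bird_id", "timestamp"] + [f"s{i}" for i in range(1, 11)]
    return pd.DataFrame(rows, columns=cols)


def _deficit_nights(daily_balances: pd.DataFrame | None, nights) -> set:
    if daily_balances is None:
        # fall back to dark nights as the deficit proxy
        return {n.date for n in nights if n.phase_class == "new"}
    neg = daily_balances[daily_balances["DEB"] < 0]
    return {pd.Timestamp(d).date() for d in neg["day"]}


def simulate_temps(
    config: SimConfig,
    nights: list[NightContext] | None = None,
    daily_balances: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly skin-temperature series plus ground-truth torpor bouts.

    Baseline ~38 °C with sensor noise; on energy-deficit nights (from
    `daily_balances`, or dark nights as proxy) a torpor bout starts
    `torpor_onset_lag_h` after the night's moonset (whole-hour
    resolution, only if still nocturnal), lasting 2–4 h at a 32–34 °C
    trough.  Bout hours are inactive; all other night hours are
    active.

    Returns (series, truth): series has bird_id, hour_start, tsk,
    active, is_night, in_migration; truth has bird_id, night_date,
    onset, end, trough.
    """
    nights = nights or simulate_nights(config)
    rng = config.rng("temps")
    deficits = _deficit_nights(daily_balances, nights)
    rows, truth = [], []
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        for night in nights:
            bout_hours: set[datetime] = set()
            trough = None
            if (
                night.date in deficits
                and night.moonset is not None
                and rng.random() < config.torpor_deficit_p
            ):
                onset = (night.moonset + timedelta(hours=config.torpor_onset_lag_h)).replace(
                    minute=0, second=0, microsecond=0
                ) + timedelta(hours=1)  # next whole hour ≥ lag after moonset
                dur = int(rng.integers(2, 5))
                end = onset + timedelta(hours=dur)
                last_night_hour = night.sunrise_next.replace(
                    minute=0, second=0, microsecond=0
                )
                if onset < last_night_hour:
                    end = min(end, last_night_hour)
                    bout_hours = {
                        onset + timedelta(hours=k)
                        for k in range(int((end - onset).total_seconds() // 3600))
                    }
                    trough = rng.uniform(*config.torpor_trough_c)
                    truth.append(
                        {
                            "bird_id": bird,
                            "night_date": night.date,
                            "onset": onset,
                            "end": end,
                            "trough": trough,
                        }
                    )
            hour = night.sunset.replace(minute=0, second=0, microsecond=0) + timedelta(
                hours=1
            )
            while hour < night.sunrise_next:
                in_bout = hour in bout_hours
                if in_bout:
                    tsk = trough + rng.normal(0.0, 0.2)
                else:
                    tsk = config.baseline_tsk_c + rng.normal(
                        0.0, config.sensor_noise_sd_c
                    )
                rows.append(
                    {
                        "bird_id": bird,
                        "hour_start": hour,
                        "tsk": round(float(tsk), 2),
                        "active": not in_bout,
                        "is_night": True,
                        "in_migration": False,
                    }
                )
                hour += timedelta(hours=1)
    series = pd.DataFrame(
        rows,
        columns=["bird_id", "hour_start", "tsk", "active", "is_night", "in_migration"],
    )
    truth_df = pd.DataFrame(
        truth, columns=["bird_id", "night_date", "onset", "end", "trough"]
    )
    return series, truth_df


def _gizzard_score_at(hours_since_sunset: float, phase_class: str, rng) -> int:
    """Nightly gizzard-score trajectory: dark nights decay, moonlit plateau."""
    if phase_class == "new":
        expected = max(0.5, 4.0 - 0.45 * hours_since_sunset)
    elif phase_class == "full":
        expected = 3.0 if hours_since_sunset < 2 else 2.5
    else:
        expected = 3.5 - 0.2 * hours_since_sunset
    return int(np.clip(round(expected + rng.normal(0, 0.4)), 0, 4))


def simulate_captures(
    config: SimConfig, nights: list[NightContext] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Capture table plus ground truth (true FDR, mass-peak lag, onset).

    Masses: lean base + lunar sinusoid (peak `mass_peak_lag_days`
    after full moon) + fueling ramp (true_fdr_g_day after fuel_onset)
    + gizzard content implied by the sampled score + noise.

    Returns (captures, truth): captures has bird_id, timestamp, mass,
    gizzard_score, fat_score, brood_patch, n_molt, sex.
    """
    nights = nights or simulate_nights(config)
    rng = config.rng("captures")
    rows = []
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        lean = config.lean_mass_g + rng.normal(0.0, 2.0)
        sex = "F" if b % 2 else "M"
        for night in nights:
            if rng.random() >= config.nightly_trap_p:
                continue
            hrs = rng.uniform(0.5, min(6.0, night.night_hours - 0.5))
            ts = night.sunset + timedelta(hours=float(hrs))
            # near-sinusoidal lunar oscillation: illuminated fraction
            # evaluated `mass_peak_lag_days` back, rescaled to ±amplitude,
            # so mass peaks that many days after full moon
            lagged = ephemeris.moon_illumination(
                ts - timedelta(days=config.mass_peak_lag_days)
            )
            sinus = config.lunar_amplitude_g * (2.0 * lagged - 1.0)
            onset_dt = datetime.combine(
                config.fuel_onset, datetime.min.time(), timezone.utc
            )
            fuel_days = max(0.0, (ts - onset_dt).total_seconds() / 86400.0)
            score = _gizzard_score_at(hrs, night.phase_class, rng)
            mass = (
                lean
                + sinus
                + config.true_fdr_g_day * fuel_days
                + (score / 4.0) * config.Mgimax
                + rng.normal(0.0, config.mass_noise_sd_g)
            )
            fat = int(np.clip(round(fuel_days / 8.0), 0, 6))
            rows.append(
                {
                    "bird_id": bird,
                    "timestamp": ts,
                    "mass": round(float(mass), 1),
                    "gizzard_score": score,
                    "fat_score": fat,
                    "brood_patch": 0,
                    "n_molt": 0,
                    "sex": sex,
                }
            )
    captures = pd.DataFrame(
        rows,
        columns=[
            "bird_id",
            "timestamp",
            "mass",
            "gizzard_score",
            "fat_score",
            "brood_patch",
            "n_molt",
            "sex",
        ],
    )
    truth = pd.DataFrame(
        [
            {
                "true_fdr_g_day": config.true_fdr_g_day,
                "mass_peak_lag_days": config.mass_peak_lag_days,
                "fuel_onset": config.fuel_onset,
                "lunar_amplitude_g": config.lunar_amplitude_g,
            }
        ]
    )
    return captures, truth


def _migration_nights(config: SimConfig, nights) -> dict[str, set]:
    """Per-bird migration night dates at the configured lag after full moon."""
    if config.n_flight_nights <= 0:
        return {}
    rng = config.rng("gps")
    fms = ephemeris.full_moon_dates(config.start, config.end)
    if not fms:
        return {}
    fm = fms[-1]  # depart around the lag after the season's last full moon
    out: dict[str, set] = {}
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        lag = config.migration_lag_days + rng.integers(-1, 2)
        dep = (fm + timedelta(days=float(lag))).date()
        dates = {
            dep + timedelta(days=k)
            for k in range(config.n_flight_nights)
            if config.start <= dep + timedelta(days=k) <= config.end
        }
        out[bird] = dates
    return out


def simulate_gps_and_migration(
    config: SimConfig, nights: list[NightContext] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nightly GPS fixes plus ground-truth migration nights.

    One fix per night near local solar midnight: stationary jitter
    (< 10 km) around the site until departure, then 150–400 km per
    migration night toward the south-southwest, then stationary again
    at the arrival location.

    Returns (fixes, truth): fixes has bird_id, timestamp, lat, lon;
    truth has bird_id, night_date.
    """
    nights = nights or simulate_nights(config)
    mig = _migration_nights(config, nights)
    rng = config.rng("gps")
    rng = np.random.default_rng(rng.integers(2**31))  # decouple from lag draws
    rows, truth = [], []
    for b in range(config.n_birds):
        bird = f"B{b:02d}"
        lat, lon = config.site.latitude, config.site.longitude
        mig_dates = sorted(mig.get(bird, set()))
        for night in nights:
            if night.date in mig_dates:
                km = rng.uniform(*config.flight_km_range)
                bearing = np.radians(rng.uniform(185.0, 205.0))
                lat += (km / 111.2) * np.cos(bearing)
                lon += (km / (111.2 * np.cos(np.radians(lat)))) * np.sin(bearing)
                truth.append({"bird_id": bird, "night_date": night.date})
            jit_km = rng.uniform(0.0, 3.0)
            jit_b = rng.uniform(0.0, 2 * np.pi)
            ts = night.sunset + (night.sunrise_next - night.sunset) / 2
            rows.append(
                {
                    "bird_id": bird,
                    "timestamp": ts,
                    "lat": round(lat + (jit_km / 111.2) * np.cos(jit_b), 5),
                    "lon": round(
                        lon
                        + (jit_km / (111.2 * np.cos(np.radians(lat)))) * np.sin(jit_b),
                        5,
                    ),
                }
            )
    fixes = pd.DataFrame(rows, columns=["bird_id", "timestamp", "lat", "lon"])
    truth_df = pd.DataFrame(truth, columns=["bird_id", "night_date"])
    return fixes, truth_df


def simulate_dataset(config: SimConfig, outdir) -> dict[str, str]:
    """Write the full synthetic dataset (CSVs + truth/ sidecars) to `outdir`."""
    from . import io as mio
    from . import energetics

    outdir = mio.ensure_dir(outdir)
    truthdir = mio.ensure_dir(outdir / "truth")
    nights = simulate_nights(config)
    paths = {}

    hourly = simulate_hourly_activity(config, nights)
    paths["hourly"] = mio.write_csv(hourly, outdir / "hourly_activity.csv")

    balances = []
    for bird, sub in hourly.groupby("bird_id"):
        states = energetics.run_energy_model(sub)
        db = energetics.daily_balance(states)
        db.insert(0, "bird_id", bird)
        balances.append(db)
    daily = pd.concat(balances, ignore_index=True)
    paths["daily"] = mio.write_csv(daily, outdir / "daily_balance.csv")

    series, torpor_truth = simulate_temps(
        config, nights, daily_balances=daily.groupby("day", as_index=False)["DEB"].mean()
    )
    paths["temps"] = mio.write_csv(series, outdir / "temps.csv")
    paths["torpor_truth"] = mio.write_csv(torpor_truth, truthdir / "torpor.csv")

    captures, cap_truth = simulate_captures(config, nights)
    paths["captures"] = mio.write_csv(captures, outdir / "captures.csv")
    paths["capture_truth"] = mio.write_csv(cap_truth, truthdir / "captures.csv")

    gps, mig_truth = simulate_gps_and_migration(config, nights)
    paths["gps"] = mio.write_csv(gps, outdir / "gps.csv")
    paths["migration_truth"] = mio.write_csv(mig_truth, truthdir / "migration.csv")

    paths["nights"] = mio.write_csv(
        ephemeris.nights_table(config.site, [n.date for n in nights]),
        outdir / "nights.csv",
    )
    return paths
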