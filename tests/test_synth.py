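"""Generator determinism, structural fidelity, and ground-truth wiring."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from moonbudget import activity as act
from moonbudget import energetics, synth, thermo
from moonbudget.synth import SimConfig


def _tiny(**kw):
    defaults = dict(seed=4, n_birds=2, start=date(2017, 7, 18), end=date(2017, 7, 27))
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        a = synth.simulate_dataset(_tiny(), tmp_path / "a")
        b = synth.simulate_dataset(_tiny(), tmp_path / "b")
        for name in a:
            assert open(a[name], "rb").read() == open(b[name], "rb").read(), name

    def test_different_seed_differs(self, tmp_path):
        a = synth.simulate_dataset(_tiny(), tmp_path / "a")
        c = synth.simulate_dataset(_tiny(seed=5), tmp_path / "c")
        assert open(a["hourly"], "rb").read() != open(c["hourly"], "rb").read()


class TestBursts:
    def test_flight_probability_zero_means_no_flight_bursts(self):
        cfg = _tiny(
            dusk_peak_p=0, dusk_peak_dark_p=0, dawn_peak_p=0, dawn_peak_dark_p=0,
            night_moonlit_p=0, night_dark_p=0, day_p=0, n_flight_nights=0,
            end=date(2017, 7, 19),
        )
        df = synth.simulate_bursts(cfg)
        flights = [
            act.classify_burst([row[f"s{i}"] for i in range(1, 11)])
            for _, row in df.iterrows()
        ]
        assert not any(flights)

    def test_moonlit_nights_more_active_than_dark_late_hours(self, summer_sim):
        """Hourly tf on moonlit nights exceeds dark late-night tf on average."""
        cfg, nights, hourly = summer_sim
        by_date = {n.date: n for n in nights}
        ts = pd.to_datetime(hourly["hour_start"])
        anchor = [
            t.date() if t.hour >= 12 else t.date() - timedelta(days=1) for t in ts
        ]
        phase = [by_date[a].phase_class if a in by_date else None for a in anchor]
        is_mid = []
        for t, a in zip(ts, anchor):
            n = by_date.get(a)
            is_mid.append(
                n is not None
                and n.sunset + timedelta(hours=1, minutes=30) <= t
                and t + timedelta(hours=1) <= n.sunrise_next - timedelta(hours=1, minutes=30)
            )
        df = hourly.assign(phase=phase, mid=is_mid)
        mid = df[df["mid"] & (df["tmr"] == 0)]
        moonlit = mid[mid["phase"] == "full"]["tf"].mean()
        dark = mid[mid["phase"] == "new"]["tf"].mean()
        assert moonlit > dark + 0.3

    def test_schedule_counts_per_tag_version(self):
        one_day = _tiny(end=date(2017, 7, 18), n_birds=1)
        df16 = synth.simulate_bursts(one_day)
        df18 = synth.simulate_bursts(_tiny(end=date(2017, 7, 18), n_birds=1, tag_version="2018"))
        per_5min_16 = df16.groupby(df16["timestamp"].dt.floor("5min")).size()
        per_5min_18 = df18.groupby(df18["timestamp"].dt.floor("5min")).size()
        assert set(per_5min_16) == {10}
        assert set(per_5min_18) == {5}


class TestTemps:
    def test_zero_torpor_probability_gives_no_bouts(self, june_july_nights):
        cfg = _tiny(torpor_deficit_p=0.0)
        series, truth = synth.simulate_temps(cfg, june_july_nights)
        assert truth.empty
        for _, sub in series.groupby("bird_id"):
            summ = thermo.skin_temp_summary(sub)
            assert thermo.detect_torpor(sub, summ) == []

    def test_baseline_only_hi_matches_noise_level(self, june_july_nights):
        """With no bouts, per-night HI ≈ the sensor noise SD."""
        cfg = _tiny(torpor_deficit_p=0.0, n_birds=1)
        series, _ = synth.simulate_temps(cfg, june_july_nights)
        his = []
        sub = series.sort_values("hour_start")
        mode = thermo.modal_temperature(sub["tsk"])
        for _, night in sub.groupby(sub["hour_start"].dt.date):
            if len(night) >= 2:
                his.append(thermo.heterothermy_index(night["tsk"], mode=mode))
        assert np.mean(his) == pytest.approx(cfg.sensor_noise_sd_c, abs=0.15)

    def test_injected_bouts_recovered_exactly(self, june_july_nights):
        """Detection at 2 SD finds every injected bout, onset within ±1 h."""
        cfg = SimConfig(seed=9, n_birds=5, start=date(2017, 6, 15), end=date(2017, 7, 31))
        series, truth = synth.simulate_temps(cfg, june_july_nights)  # dark-night proxy
        assert len(truth) > 0
        for bird, sub in series.groupby("bird_id"):
            summ = thermo.skin_temp_summary(sub)
            events = thermo.detect_torpor(sub, summ, k_sd=2)
            for _, row in truth[truth["bird_id"] == bird].iterrows():
                matches = [
                    e for e in events
                    if abs((e.onset - row["onset"]).total_seconds()) <= 3600
                ]
                assert matches, f"bout at {row['onset']} not recovered for {bird}"

    def test_torpor_fraction_peaks_near_new_moon(self, june_july_nights):
        cfg = SimConfig(seed=10, n_birds=8, start=date(2017, 6, 15), end=date(2017, 7, 31))
        series, _ = synth.simulate_temps(cfg, june_july_nights)
        events = {}
        for bird, sub in series.groupby("bird_id"):
            summ = thermo.skin_temp_summary(sub)
            events[bird] = thermo.detect_torpor(sub, summ)
        dates = [n.date for n in june_july_nights]
        frac = thermo.torpor_fraction(events, dates, birds_with_data=list(events))
        new_moon = next(
            n.date for n in june_july_nights if n.phase_class == "new"
        )
        peak_date = frac.idxmax()
        new_dates = [n.date for n in june_july_nights if n.phase_class == "new"]
        assert min(abs((peak_date - d).days) for d in new_dates) <= 3


class TestCaptures:
    def test_zero_amplitude_scan_flags_no_signal(self):
        from moonbudget import lifecycle

        cfg = SimConfig(
            seed=12, n_birds=12, start=date(2017, 5, 1), end=date(2017, 7, 31),
            lunar_amplitude_g=0.0, fuel_onset=date(2017, 12, 31),
            nightly_trap_p=0.3, n_flight_nights=0,
        )
        caps, _ = synth.simulate_captures(cfg)
        corr = [
            lifecycle.gizzard_corrected_mass(m, s)
            for m, s in zip(caps["mass"], caps["gizzard_score"])
        ]
        res = lifecycle.phase_shift_scan(
            np.array(corr), list(caps["timestamp"]), groups=caps["bird_id"].to_numpy()
        )
        assert res.no_signal

    def test_gizzard_scores_decline_on_dark_nights(self, june_july_nights):
        cfg = SimConfig(seed=13, n_birds=20, start=date(2017, 6, 15), end=date(2017, 7, 31),
                        nightly_trap_p=0.6, n_flight_nights=0)
        caps, _ = synth.simulate_captures(cfg, june_july_nights)
        by_date = {n.date: n for n in june_july_nights}
        ts = pd.to_datetime(caps["timestamp"])
        anchor = [t.date() if t.hour >= 12 else t.date() - timedelta(days=1) for t in ts]
        phase = [by_date[a].phase_class for a in anchor]
        hrs = [
            (t - by_date[a].sunset).total_seconds() / 3600 for t, a in zip(ts, anchor)
        ]
        df = caps.assign(phase=phase, hrs=hrs)
        dark = df[df["phase"] == "new"]
        early = dark[dark["hrs"] < 2]["gizzard_score"].mean()
        late = dark[dark["hrs"] > 4]["gizzard_score"].mean()
        assert early > late


class TestGps:
    def test_no_migration_all_stationary(self, june_july_nights):
        cfg = _tiny(n_flight_nights=0)
        gps, truth = synth.simulate_gps_and_migration(cfg, june_july_nights)
        assert truth.empty
        fixes = [
            act.GpsFix(r.bird_id, r.timestamp.to_pydatetime(), r.lat, r.lon)
            for r in gps.itertuples()
        ]
        disp = act.daily_displacement(fixes)
        assert not disp["moving"].any()

    def test_migration_nights_detected_exactly(self, june_july_nights):
        cfg = SimConfig(seed=1, n_birds=5, start=date(2017, 6, 15), end=date(2017, 7, 31))
        gps, truth = synth.simulate_gps_and_migration(cfg, june_july_nights)
        fixes = [
            act.GpsFix(r.bird_id, r.timestamp.to_pydatetime(), r.lat, r.lon)
            for r in gps.itertuples()
        ]
        disp = act.daily_displacement(fixes)
        detected = {
            (r.bird_id, r.date - timedelta(days=1)) for r in disp[disp["moving"]].itertuples()
        }
        injected = {(r.bird_id, r.night_date) for r in truth.itertuples()}
        assert detected == injected


class TestEnergyCoupling:
    def test_annual_range_spans_deficit_and_surplus(self, summer_sim):
        cfg, nights, hourly = summer_sim
        debs = []
        for bird, sub in hourly.groupby("bird_id"):
            states = energetics.run_energy_model(sub)
            db = energetics.daily_balance(states)
            debs.append(db[db["complete"] & (db["n_hours"] == 24)])
        deb = pd.concat(debs)["DEB"]
        assert deb.min() < -20  # new-moon deficits
        assert deb.max() > 50  # moonlit surpluses
        assert deb.between(-250, 160).all()
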