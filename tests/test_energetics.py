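"""Digestive parameters, allometric rates, and the hourly gizzard model."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moonbudget import energetics as en
from moonbudget.energetics import EnergyParams

UTC = timezone.utc
P = EnergyParams()


class TestGizzardCapacity:
    def test_published_strata_means_give_capacity(self, capture_frame):
        capacity, lean_frac = en.estimate_gizzard_capacity(capture_frame)
        assert capacity == pytest.approx(98.86 - 87.14, abs=1e-9)
        assert lean_frac == pytest.approx(11.72 / 87.14, rel=1e-6)

    def test_confounded_records_excluded(self, capture_frame):
        """Fat or brooding birds must not enter either stratum."""
        capacity, _ = en.estimate_gizzard_capacity(capture_frame)
        # the fat score-4 bird (140 g) and brooding score-0 bird (60 g)
        # would inflate the contrast to ~50 g if not filtered
        assert capacity < 15.0

    def test_empty_stratum_named_in_error(self, capture_frame):
        only_full = capture_frame[capture_frame["gizzard_score"] == 4]
        with pytest.raises(ValueError, match="empty"):
            en.estimate_gizzard_capacity(only_full)

    def test_identical_means_warn_zero(self):
        df = pd.DataFrame(
            {
                "mass": [90.0, 90.0],
                "gizzard_score": [0, 4],
                "fat_score": [0, 0],
                "brood_patch": [0, 0],
            }
        )
        with pytest.warns(UserWarning):
            capacity, _ = en.estimate_gizzard_capacity(df)
        assert capacity == 0.0


def _repeat_frame(pairs):
    rows = []
    for bird, (m0, m1, dt_h) in pairs.items():
        t0 = datetime(2017, 7, 1, 22, tzinfo=UTC)
        rows.append({"bird_id": bird, "timestamp": t0, "mass": m0})
        rows.append({"bird_id": bird, "timestamp": t0 + timedelta(hours=dt_h), "mass": m1})
    return pd.DataFrame(rows)


class TestProcessingRate:
    def test_direct_arithmetic(self):
        """1.579 g lost over 1 h at fa 0.113 → 1.780 g/h."""
        res = en.estimate_processing_rate(_repeat_frame({"a": (90.0, 88.421, 1.0)}))
        assert res.per_bird.loc[0, "rate"] == pytest.approx(1.579 / 0.887, abs=1e-3)

    def test_zero_absorption_rate_equals_defecation_rate(self):
        res = en.estimate_processing_rate(
            _repeat_frame({"a": (90.0, 88.0, 2.0)}), fa=1e-12
        )
        assert res.per_bird.loc[0, "rate"] == pytest.approx(1.0, rel=1e-6)

    def test_short_interval_excluded(self):
        res = en.estimate_processing_rate(
            _repeat_frame({"a": (90.0, 89.0, 19 / 60), "b": (90.0, 89.0, 1.0)})
        )
        by = res.per_bird.set_index("bird_id")
        assert by.loc["a", "excluded"] == "interval < 20 min"
        assert by.loc["b", "excluded"] is None

    def test_outlier_flagged_and_removed_from_max_potential(self):
        pairs = {f"b{i}": (90.0, 90.0 - loss, 1.0) for i, loss in enumerate(
            [0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4, 3.0]  # 3.0 ≥ 1.9 × 1.4
        )}
        res = en.estimate_processing_rate(_repeat_frame(pairs))
        assert res.outlier_ids == ("b7",)
        assert res.max_potential_rate < 3.0 / 0.887


class TestAllometry:
    def test_fmr_at_population_mean_mass(self):
        assert en.fmr_allometric(87.13) == pytest.approx(127.24, abs=0.005)

    def test_bmr_at_population_mean_mass(self):
        assert en.bmr_allometric(87.13) == pytest.approx(39.91, abs=0.005)

    def test_bmr_is_31_percent_of_fmr(self):
        ratio = en.bmr_allometric(87.13) / en.fmr_allometric(87.13)
        assert ratio == pytest.approx(0.31, abs=0.005)

    def test_unit_mass_collapses_to_coefficients(self):
        assert en.fmr_allometric(1.0) == pytest.approx(6.35)
        assert en.bmr_allometric(1.0) == pytest.approx(6.13 * 24e-3 * 20.51, rel=1e-9)

    def test_fmr_monotone_in_mass(self):
        masses = np.linspace(10, 200, 50)
        values = [en.fmr_allometric(m) for m in masses]
        assert np.all(np.diff(values) > 0)

    @pytest.mark.parametrize("func", [en.fmr_allometric, en.bmr_allometric])
    def test_nonpositive_mass_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.0)


class TestStepGizzard:
    def test_empty_idle_stays_empty(self):
        assert en.step_gizzard(0.0, 0.0, P) == (0.0, 0.0, 0.0)

    def test_full_gizzard_full_foraging_steady_state(self):
        """At capacity with tf=1 the gizzard refills exactly what it processes."""
        mgi, fi, fp = en.step_gizzard(P.Mgimax, 1.0, P)
        assert fp == pytest.approx(P.processing_rate)
        assert fi == pytest.approx(P.processing_rate)
        assert mgi == pytest.approx(P.Mgimax)

    def test_processing_limited_by_content(self):
        mgi, fi, fp = en.step_gizzard(1.0, 0.0, P)
        assert fp == pytest.approx(1.0)
        assert mgi == pytest.approx(0.0)

    @given(
        tfs=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_content_bounded_and_mass_conserved(self, tfs):
        """Mgi never leaves [0, Mgimax]; ΣFi − ΣFp equals the content change."""
        mgi, total_fi, total_fp = 0.0, 0.0, 0.0
        for tf in tfs:
            mgi_new, fi, fp = en.step_gizzard(mgi, tf, P)
            assert -1e-12 <= mgi_new <= P.Mgimax + 1e-9
            assert fi >= 0 and fp >= 0
            assert mgi_new == pytest.approx(mgi + fi - fp, abs=1e-9)
            mgi, total_fi, total_fp = mgi_new, total_fi + fi, total_fp + fp
        assert total_fi - total_fp == pytest.approx(mgi, abs=1e-9)


class TestHourlyEnergy:
    def test_processing_credited_energy(self):
        mei, _, _ = en.hourly_energy(0.0, 1.78, 0.0, 0.0, P)
        assert mei == pytest.approx(1.78 * 0.36 * 27.2 * 0.77, rel=1e-9)

    def test_resting_hour_costs_fmr_share(self):
        _, ee, heb = en.hourly_energy(0.0, 0.0, 0.0, 0.0, P)
        assert ee == pytest.approx(127.24 / 24, abs=1e-3)
        assert heb == pytest.approx(-127.24 / 24, abs=1e-3)

    def test_energy_linear_in_processed_mass(self):
        m1, _, _ = en.hourly_energy(0.0, 1.0, 0.0, 0.0, P)
        m2, _, _ = en.hourly_energy(0.0, 2.0, 0.0, 0.0, P)
        assert m2 == pytest.approx(2 * m1)

    def test_intake_credited_variant(self):
        p = EnergyParams(intake_credited=True)
        mei, _, _ = en.hourly_energy(2.0, 0.5, 0.0, 0.0, p)
        assert mei == pytest.approx(2.0 * p.energy_per_g_wet)


def _hourly_frame(n_hours, tf=0.0, tmr=0.0, start=None):
    start = start or datetime(2017, 7, 1, 12, tzinfo=UTC)
    return pd.DataFrame(
        {
            "hour_start": [start + timedelta(hours=h) for h in range(n_hours)],
            "tf": tf,
            "tmr": tmr,
        }
    )


class TestDailyBalance:
    def test_idle_day_loses_exactly_fmr(self):
        states = en.run_energy_model(_hourly_frame(24))
        db = en.daily_balance(states)
        full = db[db["complete"]]
        assert len(full) == 1
        assert full.iloc[0]["DEB"] == pytest.approx(-en.fmr_allometric(P.Mb), rel=1e-9)

    def test_midday_to_midday_windows(self):
        start = datetime(2017, 7, 1, 6, tzinfo=UTC)  # straddles a midday boundary
        states = en.run_energy_model(_hourly_frame(24, start=start))
        db = en.daily_balance(states)
        assert not db["complete"].all()
        assert db["n_hours"].sum() == 24

    def test_energy_consistency_total(self):
        """Σ MEi equals processed mass times the energy density exactly."""
        rng = np.random.default_rng(7)
        df = _hourly_frame(96)
        df["tf"] = rng.uniform(0, 1, len(df))
        states = en.run_energy_model(df)
        assert states["MEi"].sum() == pytest.approx(
            states["Fp"].sum() * P.energy_per_g_wet, rel=1e-12
        )


class TestScenarios:
    def test_dark_breeding_night(self):
        assert en.scenario_night_intake(9.0, False) == pytest.approx(176.7, abs=0.05)

    def test_moonlit_breeding_night(self):
        assert en.scenario_night_intake(9.0, True) == pytest.approx(210.3, abs=0.05)

    def test_moonlit_nonbreeding_night(self):
        assert en.scenario_night_intake(12.0, True) == pytest.approx(250.5, abs=0.05)

    def test_short_moonlit_night_equals_dark(self):
        """Below the retention time there is no refeeding window."""
        assert en.scenario_night_intake(5.0, True) == en.scenario_night_intake(5.0, False)

    @given(night_hours=st.floats(min_value=0.5, max_value=16.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_moonlit_never_below_dark(self, night_hours):
        moonlit = en.scenario_night_intake(night_hours, True)
        dark = en.scenario_night_intake(night_hours, False)
        assert moonlit >= dark
        if night_hours <= P.retention_hours:
            assert moonlit == dark

    def test_nonpositive_night_rejected(self):
        with pytest.raises(ValueError):
            en.scenario_night_intake(0.0, True)


class TestParams:
    def test_foraging_rate_is_capacity_per_tmax(self):
        assert P.FR == pytest.approx(11.72 * 6.0)

    def test_foraging_flight_cost_multiplier(self):
        assert P.Ef == pytest.approx(1.25 * P.Emr)

    def test_default_flight_cost_matches_power_curve(self):
        assert P.Emr == pytest.approx(en.flight_power_kj_per_h(), abs=0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(fa=1.5)
        with pytest.raises(ValueError):
            EnergyParams(Mgimax=-1.0)
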