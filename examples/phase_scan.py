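"""Lunar-phase timing: shift scan and circular event peaks.

Simulates a capture table whose gizzard-corrected masses peak 6 days
after full moon, then scans integer day-shifts of the moon-illumination
signal for the best mixed-model fit; separately, maps simulated
migration departure nights onto the lunar cycle and finds their
circular-density peak.
"""

from datetime import date

import numpy as np

from moonbudget import event_timing_vs_moon, full_moon_dates, gizzard_corrected_mass, phase_shift_scan
from moonbudget.synth import SimConfig, simulate_captures, simulate_gps_and_migration

cfg = SimConfig(
    seed=15, n_birds=15, start=date(2017, 5, 1), end=date(2017, 7, 31),
    fuel_onset=date(2017, 12, 31), nightly_trap_p=0.3, n_flight_nights=0,
)
caps, truth = simulate_captures(cfg)
corrected = np.array(
    [gizzard_corrected_mass(m, s) for m, s in zip(caps["mass"], caps["gizzard_score"])]
)
scan = phase_shift_scan(
    corrected, list(caps["timestamp"]), groups=caps["bird_id"].to_numpy()
)
print(
    f"Phase-shift scan over {len(caps)} captures: best shift "
    f"{scan.best_shift} days (injected mass-peak lag: "
    f"{truth.iloc[0]['mass_peak_lag_days']:.0f} days after full moon)"
)

mig_cfg = SimConfig(seed=16, n_birds=10, start=date(2017, 5, 1), end=date(2017, 7, 31))
_, mig_truth = simulate_gps_and_migration(mig_cfg)
departures = mig_truth.groupby("bird_id")["night_date"].min()
fms = full_moon_dates(date(2017, 5, 1), date(2017, 7, 31))
timing = event_timing_vs_moon(list(departures), fms)
print(
    f"Migration departures: circular-density peak at lunar-cycle day "
    f"{timing.peak_day:.1f} (configured lag {mig_cfg.migration_lag_days:.0f}), "
    f"Rayleigh p = {timing.rayleigh_p:.2g}"
)
print(
    "Both analyses read the timing of a response off the 29.53-day lunar "
    "cycle: the scan by refitting a model against time-shifted moonlight, "
    "the circular density by folding event dates onto days-since-full-moon."
)
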