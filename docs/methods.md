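# Methods

## Scope and shape

`moonbudget` is a library for lunar-cycle energetics of nocturnal
insectivorous birds, organised around the *night* (anchored to the
evening's calendar date, sunset → next sunrise, with an analysis
window of [sunset − 1 h, sunrise − 2 h] matching when the birds can be
observed). All timestamps are UTC; site local time is display-only.
The public face is the importable API plus `examples/`; a thin click
CLI wraps the same functions for shell pipelines over CSV files.

## Ephemeris

Sun and moon positions come from standard low-precision closed-form
series (truncated Keplerian solar longitude; lunar longitude/latitude/
distance with the leading evection-free terms), good to about a minute
for event times and ~0.01 in illuminated fraction. Rise/set events are
found by scanning geometric altitude on a one-minute grid and linearly
interpolating the horizon crossing; thresholds are −0.833° for the sun
(refraction + semidiameter) and +0.125° for the moon (refraction +
semidiameter − parallax). This is deliberately simple: the analysis
bins moon phase at 15%/85% illuminated-fraction thresholds and counts
moonlight hours per night, so minute-level accuracy is ample.
Atmospheric refinements and topocentric parallax are out of scope.

The illuminated fraction of a night is evaluated at local solar
midnight (midpoint of sunset and the next sunrise); the evaluation
instant is configurable since the fraction changes by ~0.03 over a
night. Phase classes: new < 0.15, full > 0.85, else intermediate.
Moonrise/moonset are reported only when the crossing falls inside the
night window — a moon already up at sunset has no nocturnal moonrise.

The test suite cross-checks event times against a second, independent
implementation (the closed-form NOAA sunrise equation) and anchors the
illumination model at eclipse instants, which are unambiguous full/new
moons.

## Energy model

Parameters live in a single frozen `EnergyParams` dataclass:

| parameter | default | units | meaning |
|---|---|---|---|
| Mgimax | 11.72 | g wet | gizzard capacity (full−empty strata contrast) |
| tmax_min | 10 | min | time to fill an empty gizzard |
| processing_rate | 1.78 | g wet/h | gut throughput ceiling |
| retention_hours | 6.5 | h | time to empty a full gizzard (see below) |
| fa | 0.113 | — | absorbed fraction of processed mass |
| Em_prey | 27.2 | kJ/g dry | energy density of moth prey |
| Rdw | 0.36 | — | dry:wet ratio of gizzard contents |
| mec | 0.77 | — | metabolizable energy coefficient (arthropods) |
| fmr_a, fmr_b | 6.35, 0.671 | kJ/day | FMR allometry (arid-zone birds) |
| bmr_a, bmr_b | 6.13, −0.422 | ml O₂/(g·h) | BMR allometry |
| oxy_equiv | 20.51 | kJ/l O₂ | oxygen energy equivalent |
| Emr | 8.6 | kJ/h | migratory flight cost |
| Ef_multiplier | 1.25 | — | foraging flights cost 25% more than cruising |
| Mb | 87.13 | g | population mean lean mass |

Metabolizable energy is credited when food is **processed** (Fp), not
ingested: the scenario arithmetic (two gizzard-loads on a dark night;
processing-limited refeeding on a moonlit one) is only consistent with
processing-limited assimilation, and it keeps energy bookkeeping exact
(Σ MEi = Σ Fp × Rdw × Em × mec). An intake-credited variant is kept
behind `intake_credited` for sensitivity analysis.

Within an hour the order of operations is intake, then processing,
then the capacity clip; intake is capped by the headroom left after
processing and processing by the content available including the
hour's intake, which makes mass conservation exact rather than
approximate (property-tested over random activity sequences). With
1-h steps and the default rates the ordering ambiguity is below
FR·Δt and does not affect daily sums.

`retention_hours` defaults to 6.5 h — the headline figure the nightly
scenarios are built on — rather than the unrounded quotient
Mgimax/processing_rate = 6.58 h, which remains available as
`gizzard_retention_time()`. The scenarios are idealisations: a dark
night yields exactly two full gizzard-loads regardless of how reduced
dawn foraging may be in the field; that choice is kept because it is
the published formulation, and the hourly model (not the scenario)
is the tool for realistic nights.

`Emr` cannot be measured here (the flapping-wake aerodynamic model
and the wing-morphology table behind the original estimate are out of
scope), so the default comes from the bundled fixed-wing power curve
(`flight_power_kj_per_h`: induced + parasite + profile mechanical
power at 10 m/s, muscle efficiency 0.23, respiration overhead 1.1),
rounded to 8.6 kJ/h at nightjar morphology. It is an
order-of-magnitude constant, clearly labelled as such; a simulated
migration night then runs a strongly negative balance (≈ −200
kJ/day), comfortably beyond the ±100 kJ/day envelope of ordinary
nights. FMR is apportioned uniformly as FMR/24 per hour since only a
daily allometric value exists.

Daily balances sum hourly values over [12:00, 12:00) UTC windows
labelled by the starting date, so a window contains one whole night;
windows missing hours are flagged incomplete rather than summed
silently.

## Skin temperature

The heterothermy index is HI = sqrt(Σ(T_mod − T_i)²/(n−1)) against the
bird's modal skin temperature. The mode uses a 0.5 °C-binned histogram
of nighttime records, returning the mean of records in the fullest bin
(ties to the lowest bin) so that HI is exactly zero on constant series
and exactly translation-invariant for whole-bin shifts; arbitrary
shifts can move records across a bin edge and perturb HI by at most
the bin width. Reference mean/SD come from *active* nighttime
non-migration records (the normothermic operating range); daytime
records are excluded because dorsally mounted sensors are
solar-heated, and migration hours because altitude cools the sensor.

Torpor events are maximal runs of inactive nocturnal hours below
(mean − k·SD), k = 2 by default and 3 as the conservative sensitivity
setting; the mode can be substituted as the anchor by flag. A single
sub-threshold hour counts as a bout (hourly sensor resolution makes
shorter bouts invisible); a minimum duration is configurable. Onset
lag is signed hours from the night's moonset, with nights lacking a
nocturnal moonset excluded.

## Activity and movement

A burst is flight when ≥3 demeaned samples exceed |g/3|; mean
subtraction removes static gravity, making the rule offset-invariant.
The ≥3-exceedance count is kept absolute for 5-sample bursts (the
sampling schedule, not the burst length, is what differs between tag
generations). Hourly foraging fraction tf is flight-positive bursts
over total bursts in the clock hour, with hours inside migration
segments reassigned to tmr; hours with no bursts are missing, not
zero.

Migration segmentation: core flight hours have every 5-min activity
value positive and an hourly mean at or above the tag-version
threshold (6 on the 0–10 scale for 2016–17 tags, 3 on the 0–5 scale
for 2018); maximal runs of core hours are extended at each end by
5 min per at-threshold interval in the adjacent hour, then merged. A
night counts as a migratory-flight night with ≥1 h of segment overlap
or a GPS displacement > 10 km.

GPS daily displacement uses one representative fix per UTC calendar
date — the fix closest to local solar midnight, since the birds move
at night — and the haversine great-circle distance on a 6371-km
sphere, with a 10-km stationary/movement threshold. Days are keyed by
UTC date deliberately: keying by local solar date lets the day
boundary drift as a migrating bird crosses meridians.

## Lifecycle analyses

Body masses are gizzard-corrected assuming content linear in the 0–4
palpation score ((score/4)·Mgimax). Fuel deposition rate is the
first-to-last change in corrected mass over days elapsed, per bird,
excluding birds with any incubation/gravid record (brood-patch 3);
this definition is invariant to intermediate captures. Note an
estimator property verified by the tests: when body mass also
oscillates with the lunar cycle, first-to-last differencing aliases
the oscillation into the rate with error of order amplitude/interval
(≈ 0.01–0.03 g/day at 1.2 g amplitude over 2–6 weeks) unless the
monitoring window spans whole synodic cycles. The original analysis
handled this by modelling moonlight explicitly; users of the plain
estimator should either monitor over whole cycles or treat the bound
2·amplitude/interval as the systematic error.

Breakpoint onsets (fueling start from fat scores, molt period from
molt counts) use a continuous two-segment least-squares fit with the
break grid-searched over interior observed days (≥2 points per side);
a flat RSS profile means no identifiable break and is flagged with a
warning.

The phase-shift scan refits `response ~ moon_fraction(date − s)` for
integer shifts s = 0..29 and reports the shift maximising conditional
R² (Nakagawa–Schielzeth: fixed + random variance over total), with a
random intercept per group via statsmodels MixedLM when groups are
given and OLS otherwise. Ties go to the smallest shift;
non-convergent shifts are excluded; a scan whose R² range is below
0.05 is flagged "no lunar signal" (the default ε absorbs the sampling
fluctuation of R² at a few hundred observations). Shifting the date
axis is equivalent to shifting the phase of a periodic signal, and
the grid is integer days because the response data are nightly.

Event timing folds event dates onto days-since-full-moon (most recent
reference full moon) and finds the peak of a wrapped-Gaussian kernel
density (period 29.53 days, bandwidth 2 days, 0.05-day grid); a
Rayleigh test reports circular uniformity. This kernel-density mode
finder is a documented stand-in for a formal multimodality test,
which is out of scope.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
using real 2017 lunar geometry from the ephemeris so sun/moon timing
is realistic without any downloads. Per-hour flight-burst
probabilities: 0.85 at dusk and 0.75 at dawn on moonlit nights,
reduced to 0.12/0.05 on dark (new-moon) nights; 0.65 × illuminated
fraction while the moon is up at night (matching sustained >60%
nocturnal activity on moonlit nights); 0.005 otherwise. The dark-night
reductions are what generate new-moon energy deficits — the hourly
model converts any appreciable dusk activity into a full gizzard
within the hour, so deficits require genuinely depressed foraging, and
the depressed dawn bout mirrors the partially filled morning gizzards
seen in the field. Torpor bouts are injected on deficit nights
(probability 0.9) starting the next whole hour ≥1 h after moonset,
2–4 h long, at a 32–34 °C trough against a 38 °C baseline with 0.3 °C
sensor noise. Capture masses combine lean mass (87.13 g ± 2 between
birds), a lunar oscillation generated as lagged illuminated fraction
rescaled to ±1.2 g and peaking 6 days after full moon, a fueling ramp
of 0.43 g/day after the configured onset, gizzard-content mass implied
by the sampled score (declining through dark nights, intermediate
plateau on moonlit nights), and 0.4 g measurement noise. Migration
departs at a configured lag (default 13 days) after the season's last
full moon with ±1 day per-bird jitter, 4 consecutive flight nights of
150–400 km; stationary GPS jitter stays below 3 km.

Every generator draws from its own seed-derived stream, so outputs are
byte-identical under a fixed seed, and each emits ground truth as
sidecar tables (never embedded in the data files) for closed-loop
recovery tests.

What the generator does **not** emulate: insect abundance and weather,
digestive plasticity, individual behavioural syndromes, sensor
drop-outs, or intake efficiency varying with gizzard fullness. Passing
recovery tests therefore demonstrate that the estimators are correct
under the assumed structure, not that the structure captures every
feature of real field data.

## Problem sizes and numerical choices

Tests exercise cohorts of 2–20 birds over 1.5–3 months at hourly
resolution, and one full-year run of 10 birds (the whole suite runs in
well under a minute of CPU); burst-level simulation is used over days
to weeks, since the analyses consume hourly aggregates. Event-time
interpolation is linear between minute-grid samples (≤1 min error).
Degenerate inputs fail loudly: polar days/nights raise, empty capacity
strata are named, short repeat-capture intervals are excluded with a
reason, and single-capture birds are skipped rather than imputed.

## Known limitations

The ephemeris is low-precision by design and unsuitable for polar
sites or astronomical work. Flight cost is a configurable constant,
not an aerodynamic model. The scenario calculator idealises dark
nights as exactly two gizzard-loads. Mixed-model machinery covers the
Gaussian random-intercept case used by the scan; binomial or
negative-binomial responses with crossed random effects would need an
external fitting tool. The torpor detector assumes hourly, regularly
sampled skin temperature.
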