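"""Per-night sun/moon context for the Doñana study site.

Builds the nightly ephemeris table for one week around a full moon and
prints it: sunset/sunrise, moonrise/moonset within the night, the
illuminated fraction, its phase class (new < 15%, full > 85%), and the
number of night hours with the moon above the horizon — the variables
that gate a nightjar's foraging window.
"""

from datetime import date, timedelta

from moonbudget import DONANA, full_moon_dates, night_context

full_moons = full_moon_dates(date(2017, 6, 1), date(2017, 6, 30))
anchor = full_moons[0].date()
print(f"Full moon instant: {full_moons[0]:%Y-%m-%d %H:%M} UTC\n")

for offset in range(-3, 4):
    ctx = night_context(DONANA, anchor + timedelta(days=offset))
    moonset = f"{ctx.moonset:%H:%M}" if ctx.moonset else "  -  "
    print(
        f"{ctx.date}  sunset {ctx.sunset:%H:%M}  sunrise {ctx.sunrise_next:%H:%M}  "
        f"moonset {moonset}  illum {ctx.illuminated_fraction:.2f}  "
        f"{ctx.phase_class:12s}  moonlight {ctx.moonlight_hours:4.1f} h"
    )

print(
    "\nAround the full moon the moon is up essentially the whole night "
    "(moonlight hours ≈ night duration), which is what sustains nocturnal "
    "foraging; within a week the moonlit window shrinks by several hours."
)
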