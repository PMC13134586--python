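from datetime import date

import pandas as pd
import pytest

from moonbudget import synth
from moonbudget.ephemeris import DONANA


@pytest.fixture(scope="session")
def june_july_nights():
    """Night contexts at the study site over one full lunar cycle + margin."""
    cfg = synth.SimConfig(start=date(2017, 6, 15), end=date(2017, 7, 31))
    return synth.simulate_nights(cfg)


@pytest.fixture(scope="session")
def summer_sim(june_july_nights):
    """A small simulated cohort (5 birds, 6.5 weeks) with hourly activity."""
    cfg = synth.SimConfig(
        seed=11, n_birds=5, start=date(2017, 6, 15), end=date(2017, 7, 31)
    )
    hourly = synth.simulate_hourly_activity(cfg, june_july_nights)
    return cfg, june_july_nights, hourly


@pytest.fixture(scope="session")
def capture_frame():
    """Lean/nonbreeding strata reproducing the published capacity contrast."""
    rows = []
    for score, mean in ((4, 98.86), (0, 87.14)):
        for delta in (-1.0, 1.0):
            rows.append(
                {
                    "bird_id": f"g{score}{delta:+.0f}",
                    "mass": mean + delta,
                    "gizzard_score": score,
                    "fat_score": 0,
                    "brood_patch": 0,
                }
            )
    # confounded records that the lean/nonbreeding filter must drop
    rows.append(
        {"bird_id": "fat", "mass": 140.0, "gizzard_score": 4, "fat_score": 5, "brood_patch": 0}
    )
    rows.append(
        {"bird_id": "brood", "mass": 60.0, "gizzard_score": 0, "fat_score": 0, "brood_patch": 3}
    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def site():
    return DONANA
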