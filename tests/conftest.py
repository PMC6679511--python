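from datetime import date

import pytest
from hypothesis import settings

from homesense import simulate as sim

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def night():
    """Night-only routine: ~21:30-07:00 active at 0.97, background 0.01."""
    return sim.night_mode(p_active=0.97, p_background=0.01, weight=0.5)


@pytest.fixture(scope="session")
def night_nap():
    """Night routine plus a 3-hour afternoon rest (13:30-16:30)."""
    return sim.nap_mode(p_active=0.97, p_background=0.01, weight=0.5,
                        nap_bins=range(27, 33))


@pytest.fixture(scope="session")
def daytime_mode():
    """A deviant all-day-in-bed pattern, far from both usual routines."""
    return sim.ModeSpec(
        "daytime", tuple(0.9 if 16 <= j < 36 else 0.02 for j in range(48)))


@pytest.fixture(scope="session")
def separated_groups(night, night_nap):
    """20 + 20 day traces from the two well-separated routines."""
    m1 = sim.ModeSpec(night.name, night.bin_probabilities, 1.0)
    m2 = sim.ModeSpec(night_nap.name, night_nap.bin_probabilities, 1.0)
    t1, _ = sim.sample_day_traces([m1], 20, seed=1)
    t2, _ = sim.sample_day_traces([m2], 20, seed=500001,
                                  start_date=date(2024, 1, 21))
    return t1, t2
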