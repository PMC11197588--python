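import numpy as np
import pandas as pd
import pytest

from maizeyield.synth import SyntheticConfig, generate_panel

# A compact panel for unit tests: 36 counties on a 6x6 grid, nine years
# around the 2012 extreme, four true regions.  Session-scoped because
# generation is deterministic and read-only.
SMALL_CONFIG = SyntheticConfig(
    n_cols=6, n_rows=6, years=tuple(range(2008, 2017)),
    n_true_regions=4, extreme_year=2012, seed=7,
)


@pytest.fixture(scope="session")
def small_panel():
    return generate_panel(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_arrays(small_panel):
    from maizeyield.panel import panel_to_arrays
    return panel_to_arrays(small_panel)


def make_daily_weather(n_days=365, tmean_amplitude=18.0, tmean_base=9.0, seed=0):
    """One synthetic calendar year of daily weather for panel-derivation tests."""
    rng = np.random.default_rng(seed)
    doy = np.arange(1, n_days + 1)
    tmean = tmean_base + tmean_amplitude * np.sin((doy - 105) / 365 * 2 * np.pi)
    spread = 5.0 + rng.uniform(0, 2, n_days)
    return pd.DataFrame({
        "day_of_year": doy,
        "tmean": tmean,
        "tmin": tmean - spread,
        "tmax": tmean + spread,
        "prcp": rng.gamma(2.0, 1.5, n_days),
        "vpdmin": rng.uniform(1, 5, n_days),
        "vpdmax": rng.uniform(8, 20, n_days),
    })


@pytest.fixture
def daily_weather():
    return make_daily_weather()
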