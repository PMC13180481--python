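import numpy as np
import pytest

from toadtrends.synthetic import TrendScenario, simulate_count_series
from toadtrends.trends import CountSeries


@pytest.fixture(scope="session")
def linear_decline_series() -> CountSeries:
    """One gap-free 15-year series with a strong log-linear decline."""
    scen = TrendScenario(
        shape="linear",
        per_year_log_change=-0.2,
        dispersion_theta=10.0,
        n_obs=15,
        gap_fraction=0.0,
        seed=42,
    )
    return simulate_count_series(scen, site_id="decline")


@pytest.fixture(scope="session")
def hump_series() -> CountSeries:
    """Gap-free 20-year series with equal endpoints and a strong mid-peak."""
    scen = TrendScenario(
        shape="hump",
        amplitude_log=1.5,
        dispersion_theta=10.0,
        n_obs=20,
        gap_fraction=0.0,
        seed=7,
    )
    return simulate_count_series(scen, site_id="hump")


@pytest.fixture(scope="session")
def noise_free_glm_series() -> CountSeries:
    """Counts that follow exp(2 + 0.1 t) exactly (rounded), t = 0..8."""
    years = np.arange(2000, 2009)
    counts = np.round(np.exp(2.0 + 0.1 * (years - 2000))).astype(int)
    return CountSeries("noise_free", list(zip(years.tolist(), counts.tolist())))
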