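import numpy as np
import pytest

from ecoskill import EcosystemConfig, PairedSeries, TimeSeries, generate_ecosystem


def make_series(values, series_id="s", category="biomass", source="observed",
                start_year=2000, units=""):
    values = np.asarray(values, dtype=float)
    years = start_year + np.arange(len(values))
    return TimeSeries(series_id, category, source, years, values, units)


def make_pair(obs, mod, series_id="s", start_year=2000):
    obs = np.asarray(obs, dtype=float)
    years = start_year + np.arange(len(obs))
    return PairedSeries(series_id, years, obs, np.asarray(mod, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_ecosystem():
    """One small synthetic ecosystem shared across read-only tests."""
    config = EcosystemConfig(n_groups=12, seed=7)
    return generate_ecosystem(config)


def random_pairs(rng, count, n_min=3, n_max=50):
    """Stream of random valid pairs with occasional ties."""
    for _ in range(count):
        n = int(rng.integers(n_min, n_max + 1))
        obs = rng.normal(0, rng.uniform(0.5, 3), size=n)
        mod = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=n)
        if rng.uniform() < 0.3:  # inject ties
            obs = np.round(obs)
            mod = np.round(mod)
        yield make_pair(obs, mod)
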