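import numpy as np
import pytest

from popspectrum.datasets import PopulationTimeSeries, ScaledSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_series():
    return PopulationTimeSeries(
        series_id="s1", species="Cervus elaphus", taxon_class="Mammalia",
        realm="terrestrial", biome="temperate broadleaf forest",
        latitude=52.1, longitude=-3.2, unit="number of individuals",
        years=np.arange(1990, 2000), abundances=np.linspace(100, 190, 10),
    )


@pytest.fixture
def noisy_scaled(rng):
    """A realistic rescaled series from a drifting random walk."""
    n = 25
    latent = 0.5 + np.cumsum(np.r_[0, rng.normal(0.01, 0.04, n - 1)])
    obs = latent + rng.normal(0, 0.03, n)
    return ScaledSeries("noisy", 1985 + np.arange(n), obs, "raw")


@pytest.fixture(scope="session")
def small_dataset():
    from popspectrum.simulate import SimulationConfig, simulate_dataset

    data, truth = simulate_dataset(
        SimulationConfig(n_series=80, n_species=25), seed=7)
    return data, truth
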