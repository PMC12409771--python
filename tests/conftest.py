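import numpy as np
import pytest

from pixelet import (BeamScenario, RecalibrationParams, RunConfig,
                     generate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helium_dataset():
    """Mid-size mixed helium field: primaries + hydrogen fragments + noise."""
    scenario = BeamScenario(species="helium", depth_pmma=42.0, n_primaries=2000,
                            fragment_fraction=0.15, noise_rate=0.2, seed=42)
    hits, truth = generate_dataset(scenario)
    return scenario, hits, truth


@pytest.fixture(scope="session")
def proton_dataset():
    scenario = BeamScenario(species="proton", depth_pmma=42.0, n_primaries=2000,
                            fragment_fraction=0.03, noise_rate=0.1, seed=7)
    hits, truth = generate_dataset(scenario)
    return scenario, hits, truth


@pytest.fixture
def default_params():
    return RecalibrationParams()


def random_spectrum(rng, n_bins=50, width=1.0, quantity="let", medium="water"):
    """A random positive-weight spectrum on a uniform grid (test helper)."""
    from pixelet import Spectrum
    edges = np.arange(n_bins + 1, dtype=float) * width
    weights = rng.gamma(2.0, 1.0, size=n_bins)
    return Spectrum(edges, weights, quantity=quantity, medium=medium)
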