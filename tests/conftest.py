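import numpy as np
import pytest

from mvmap import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def design_dataset():
    """Five historical control arms at zero heterogeneity (design phase)."""
    return generate_dataset(ScenarioConfig(J=5, heterogeneity="No", seed=123)).historical_only()


@pytest.fixture(scope="session")
def analysis_dataset():
    """Five historical arms plus a two-arm new trial, no true effect."""
    return generate_dataset(ScenarioConfig(J=5, heterogeneity="No", seed=123))
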