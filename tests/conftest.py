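import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fnirsnet import GeneratorConfig, TappingNetworkAnalysis, generate_dataset
from fnirsnet.geometry import load_channel_map

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channel_map():
    return load_channel_map()


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at the default conditions (fixed seed)."""
    config = GeneratorConfig(seed=7)
    series_list, records, truth = generate_dataset(config)
    return config, series_list, records, truth


@pytest.fixture(scope="session")
def fitted_results(default_dataset):
    """Full pipeline fit of the default synthetic study."""
    config, series_list, records, truth = default_dataset
    model = TappingNetworkAnalysis(series_list, records, ground_truth=truth)
    with np.errstate(all="ignore"):
        return model.fit()
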