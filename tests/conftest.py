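import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from foodenv.config import (
    BrandSpec,
    NoiseConfig,
    NormalizationConfig,
    SimulationConfig,
)
from foodenv.synthetic import (
    generate_universe,
    make_geography,
    render_local_view,
    render_online_view,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geography() -> pd.DataFrame:
    return make_geography()


def small_sim_config(geography: pd.DataFrame, scale: float = 1.0) -> SimulationConfig:
    """A compact universe (~320*scale outlets) with brands either side of the
    franchise boundary."""
    regions = dict(zip(geography["region"], geography["urban"]))
    per_region = {r: int((120 if urban else 40) * scale)
                  for r, urban in regions.items()}
    brands = [
        BrandSpec(name="burger barn", n_locations=max(2, int(14 * scale)),
                  subtype="unhealthy", descriptors=["fast food", "burger"]),
        BrandSpec(name="scoop city", n_locations=max(2, int(11 * scale)),
                  subtype="dessert", descriptors=["ice cream", "desserts"]),
        BrandSpec(name="corner pide", n_locations=max(1, int(10 * scale)),
                  subtype="unhealthy", descriptors=["kebab", "comfort food"]),
    ]
    return SimulationConfig(outlets_per_region=per_region, franchise_brands=brands)


@pytest.fixture(scope="session")
def sim_config(geography) -> SimulationConfig:
    return small_sim_config(geography)


@pytest.fixture(scope="session")
def norm_config(geography) -> NormalizationConfig:
    return NormalizationConfig(
        suburb_list=sorted(geography["suburb"].str.lower().unique())
    )


@pytest.fixture(scope="session")
def zero_noise_world(geography, sim_config, norm_config):
    """Universe plus both views rendered with all noise rates at zero."""
    universe = generate_universe(sim_config, geography, seed=7)
    noise = NoiseConfig.zero(seed=7)
    local_rows, local_truth = render_local_view(universe, noise,
                                                norm_config.centre_list)
    online_rows, online_truth = render_online_view(universe, geography, noise,
                                                   norm_config.centre_list)
    return {
        "universe": universe,
        "local_rows": local_rows,
        "local_truth": local_truth,
        "online_rows": online_rows,
        "online_truth": online_truth,
    }


@pytest.fixture(scope="session")
def noisy_world(geography, sim_config, norm_config):
    """Universe plus both views under the default noise rates."""
    universe = generate_universe(sim_config, geography, seed=11)
    noise = NoiseConfig(seed=11)
    local_rows, local_truth = render_local_view(universe, noise,
                                                norm_config.centre_list)
    online_rows, online_truth = render_online_view(universe, geography, noise,
                                                   norm_config.centre_list)
    return {
        "universe": universe,
        "local_rows": local_rows,
        "local_truth": local_truth,
        "online_rows": online_rows,
        "online_truth": online_truth,
    }
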