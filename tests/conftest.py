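import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from emocaccess import (
    PipelineConfig,
    SyntheticConfig,
    build_cost_surface,
    build_road_graph,
    generate_facilities,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_cfg():
    """A compact seeded landscape exercising every downstream stage."""
    return SyntheticConfig(
        seed=7,
        rows=60,
        cols=60,
        cell_size=500.0,
        n_settlements=10,
        facilities_per_level={5: 1, 4: 3, 3: 2, 2: 5, 1: 2},
        population_total=20_000.0,
    )


@pytest.fixture(scope="session")
def landscape(small_cfg):
    return generate_landscape(small_cfg)


@pytest.fixture(scope="session")
def facilities(small_cfg, landscape):
    return generate_facilities(small_cfg, landscape)


@pytest.fixture(scope="session")
def cost(landscape):
    return build_cost_surface(landscape)


@pytest.fixture(scope="session")
def road_graph(landscape):
    return build_road_graph(landscape.roads)


@pytest.fixture(scope="session")
def study_pipeline():
    """The default study conditions, run once for all four models."""
    from emocaccess import run_pipeline

    cfg = PipelineConfig(synthetic=SyntheticConfig(seed=0), upgrades=2)
    return cfg, run_pipeline(cfg)


def random_cost_surface(rng, rows, cols, impassable_frac=0.05):
    """Uniform-random crossing costs with a sprinkle of impassable cells."""
    from emocaccess import CostSurface, GridSpec

    cost = rng.uniform(0.5, 10.0, size=(rows, cols))
    blocked = rng.random((rows, cols)) < impassable_frac
    cost[blocked] = np.inf
    return CostSurface(cost=cost, grid=GridSpec(100.0, 0.0, 0.0, rows, cols))
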