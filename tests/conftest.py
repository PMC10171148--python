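import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crowdcontact.pipeline import PipelineConfig, SimulationConfig
from crowdcontact.simulate import GatheringConfig
from crowdcontact.world import WorldConfig, generate_world

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_world_config() -> WorldConfig:
    """2x2 CBG grid with one POI per CBG and a small user base."""
    return WorldConfig(grid_rows=2, grid_cols=2, n_users=80)


@pytest.fixture(scope="session")
def tiny_world(tiny_world_config):
    return generate_world(tiny_world_config, seed=7)


@pytest.fixture(scope="session")
def small_run_config() -> PipelineConfig:
    """Three-day run on a 3x3 world, small enough for second-scale tests."""
    return PipelineConfig(
        world=WorldConfig(grid_rows=3, grid_cols=3, n_users=250),
        simulation=SimulationConfig(
            days=3,
            gatherings=GatheringConfig(mean_per_day=3.0),
            daily_activity=1.0,
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_run_config):
    from crowdcontact.pipeline import run_pipeline

    return run_pipeline(small_run_config, with_outputs=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
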