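import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import microzone as mz
from microzone.pipeline import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_geom() -> mz.NetworkGeometry:
    return mz.NetworkGeometry()


@pytest.fixture(scope="session")
def mid_geom() -> mz.NetworkGeometry:
    """Reduced problem size: 20 files and 500 granule cells per field.

    Keeps all 41 ranks (the statistics of file pooling and of the sine
    drive depend on the rank count) while cutting the grid and per-field
    populations for speed.
    """
    return mz.NetworkGeometry(
        fields_per_rank=20,
        granule_per_field=500,
        glomeruli_per_field=200,
        mossy_fibres_total=350 * 41,
        terminals_per_field_target=700,
    )


@pytest.fixture(scope="session")
def mid_config(mid_geom) -> SimulationConfig:
    return SimulationConfig(geometry=mid_geom)


@pytest.fixture(scope="session")
def mid_run(mid_config) -> mz.NetworkRun:
    """One full end-to-end run at the reduced size, shared across tests."""
    return mz.simulate(mid_config, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
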