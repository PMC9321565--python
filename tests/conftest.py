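import numpy as np
import pytest

from grasscap.grids import Grid
from grasscap.synthetic import ScenarioConfig, generate_scenario

FIXTURE_SEED = 12345


def make_grid(values, cell=500.0, crs="EPSG:6933", nodata=-9999.0):
    """Small helper: grid at the origin with square cells."""
    values = np.asarray(values)
    return Grid(values, (0.0, cell, 0.0, 0.0, 0.0, -cell), crs, nodata=nodata)


@pytest.fixture(scope="session")
def scenario_config():
    return ScenarioConfig(rows=48, cols=48, rng_seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def bundle(scenario_config):
    """The reference synthetic world used across the suite."""
    return generate_scenario(scenario_config)


@pytest.fixture(scope="session")
def fixture_dir(bundle, tmp_path_factory):
    from grasscap.synthetic import write_fixture

    d = tmp_path_factory.mktemp("scenario")
    write_fixture(bundle, d)
    return d
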