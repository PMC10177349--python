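import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from grazedrivers import (
    PaddockBoundary,
    SimConfig,
    Trajectory,
    build_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return PaddockBoundary(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]), name="unit")


@pytest.fixture
def square_100m():
    return PaddockBoundary(Polygon([(0, 0), (100, 0), (100, 100), (0, 100)]), name="sq100")


@pytest.fixture
def grid_100m(square_100m):
    return build_grid(square_100m, cell_size=5.0)


@pytest.fixture
def trial_start():
    return pd.Timestamp("2014-04-23T00:00:00+10:00")


def make_trajectory(times, eastings, northings, ttf=None, animal="A01", **kw) -> Trajectory:
    n = len(times)
    fixes = pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": pd.to_datetime(times),
            "easting": np.asarray(eastings, dtype=float),
            "northing": np.asarray(northings, dtype=float),
            "ttf": np.asarray(ttf if ttf is not None else np.full(n, 5.0), dtype=float),
        }
    )
    return Trajectory(animal, fixes, **kw)


@pytest.fixture
def small_sim_config():
    """A fast-but-real trial: small flock, short day, full observation model."""
    return SimConfig(seed=3, n_animals=4, n_days=1, width=200.0, height=180.0, n_trees=12)


@pytest.fixture(scope="session")
def ip_like_bundle():
    """One seeded improved-pasture-style pipeline run shared across tests."""
    from grazedrivers import run_pipeline
    from grazedrivers.simulate import get_scenario

    cfg = get_scenario("ip-like", seed=11, n_days=1, n_animals=8)
    return run_pipeline(cfg)
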