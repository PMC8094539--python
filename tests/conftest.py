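import logging

import numpy as np
import pandas as pd
import pytest

from patchdive import GeneratorConfig, default_world, run_pipeline, simulate_dataset

logging.getLogger("patchdive").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def world():
    return default_world()


@pytest.fixture(scope="session")
def small_config():
    """A reduced season: 6 birds x 2 trips, shorter ranges, all defaults else."""
    return GeneratorConfig(
        n_birds=6, trips_per_bird=2, max_range_incubation_km=18, max_range_brood_km=8
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, world):
    return simulate_dataset(small_config, world, seed=3)


@pytest.fixture(scope="session")
def pipeline_out(small_config, world, small_dataset):
    return run_pipeline(small_config, world, seed=3, data=small_dataset)


def make_fixes(times_s, lats, lons, bird="B1", t0="2015-12-20"):
    t0 = pd.Timestamp(t0)
    return pd.DataFrame(
        {
            "bird_id": bird,
            "t": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )


def make_series(depths, dt=1.0, t0="2015-12-20"):
    t0 = pd.Timestamp(t0)
    n = len(depths)
    return pd.DataFrame(
        {
            "t": [t0 + pd.Timedelta(seconds=i * dt) for i in range(n)],
            "depth": np.asarray(depths, dtype=float),
        }
    )
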