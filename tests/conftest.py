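import numpy as np
import pytest
import shapely.geometry as sgeom

from nhbd_lab import synthetic
from nhbd_lab.availability import fit_movement_profile
from nhbd_lab.landscape import PairRegistry, StudyArea

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20180912)


@pytest.fixture(scope="session")
def small_landscape():
    """40x40 km autocorrelated landscape at 1 km resolution."""
    return synthetic.generate_landscape(
        resolution_m=1000.0,
        extent_cells=(40, 40),
        autocorr_range_m=5000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def study_area(small_landscape):
    return StudyArea(small_landscape.bounds_polygon())


@pytest.fixture(scope="session")
def square_area():
    return StudyArea(sgeom.box(0.0, 0.0, 200_000.0, 200_000.0))


@pytest.fixture(scope="session")
def profiles():
    trajs = synthetic.generate_reference_trajectories(
        n_trajectories=13, n_steps=150, seed=5
    )
    return [fit_movement_profile(t) for t in trajs]


@pytest.fixture
def empty_registry():
    return PairRegistry()


@pytest.fixture
def registry_2005():
    return PairRegistry(
        pd.DataFrame(
            {
                "year": [2005, 2005, 2005, 2006],
                "x": [50_000.0, 120_000.0, 160_000.0, 50_000.0],
                "y": [50_000.0, 120_000.0, 40_000.0, 50_000.0],
            }
        )
    )
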