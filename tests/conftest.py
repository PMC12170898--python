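import numpy as np
import pytest

from lineagemotility import synthetic_data, tracking_io
from lineagemotility.model import FateLabel


def forest_from(sim):
    fates = {r.cell_id: FateLabel(r.fate) for r in sim.fates.itertuples()}
    return tracking_io.assemble_forest(sim.spots, sim.links, sim.meta, fates)


@pytest.fixture(scope="session")
def worked():
    return synthetic_data.generate_worked_example()


@pytest.fixture(scope="session")
def worked_forest(worked):
    return forest_from(worked)


@pytest.fixture(scope="session")
def small_movie():
    """One scaled-down synthetic movie (lag 0) reused across read-only tests."""
    cfg = synthetic_data.small_config(seed=11, movie_lags_min=(0.0,), n_movies=1)
    return synthetic_data.generate_embryo(cfg, seed=11, movie_index=0)


@pytest.fixture(scope="session")
def small_forest(small_movie):
    return forest_from(small_movie)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
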