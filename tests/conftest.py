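import logging

import numpy as np
import pandas as pd
import pytest

from nightshare.config import AnalysisConfig
from nightshare.preprocess import clean_individual
from nightshare.simulate import make_scenario, simulate_gps

logging.getLogger("nightshare").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A short two-group dataset with chance sharing, reused across tests."""
    cfg, _ = make_scenario("null_independent", seed=7, n_days=20)
    gps, truth = simulate_gps(cfg)
    return cfg, gps, truth


@pytest.fixture(scope="session")
def small_tracks(small_sim, config):
    _, gps, _ = small_sim
    trajs = clean_individual(gps, config)
    return {t.group_id: t for t in trajs}


def random_walk_track(seed, n_days=4, group="GA", start="2021-03-01 12:00",
                      step=120.0, tz="+03:00"):
    """Noon-anchored random-walk Trajectory for permutation tests."""
    from nightshare.preprocess import Trajectory, OBSERVED
    rng = np.random.default_rng(seed)
    n = n_days * 96
    xy = np.cumsum(rng.normal(0, step, (n, 2)), axis=0)
    return Trajectory(f"{group}_F1", group, pd.Timestamp(f"{start}{tz}"),
                      pd.Timedelta(minutes=15), xy,
                      np.full(n, OBSERVED, np.int8))
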