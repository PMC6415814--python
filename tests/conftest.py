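"""Shared fixtures: the default community and one full default-scenario run.

The expensive session fixtures (full 30-site accident run and its
metrics table) are computed once and shared by the acceptance tests
and the metrics tests.
"""

import numpy as np
import pandas as pd
import pytest

from pelagics.config import RunConfig
from pelagics.dynamics import build_cohorts, simulate
from pelagics.metrics import metrics_table
from pelagics.pipeline import make_forcings
from pelagics.species import default_species_table


@pytest.fixture(scope="session")
def species():
    return default_species_table()


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(default_cfg):
    """Full default accident scenario: (forcings, cohorts, result)."""
    forcings = make_forcings(default_cfg)
    cohorts = build_cohorts(
        default_cfg.species(), forcings[0].dates, seed=default_cfg.seed
    )
    result = simulate(
        forcings,
        cohorts,
        cp=default_cfg.contaminant.params(),
        sel=default_cfg.selectivity.params(),
        plankton=default_cfg.plankton.params(),
    )
    return forcings, cohorts, result


@pytest.fixture(scope="session")
def default_metrics(default_cfg, default_run):
    _, _, result = default_run
    return metrics_table(result, default_cfg.scenario.accident_date)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def daily_axis():
    return pd.date_range("2002-01-01", "2013-02-28", freq="D")
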