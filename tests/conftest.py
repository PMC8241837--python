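import math

import numpy as np
import pandas as pd
import pytest

from hiermort import (BaselineHazard, Covariate, MCMCSettings, ModelSpec,
                      SimConfig, SplitGrid, fit_mcmc, simulate_dataset,
                      split_episodes)


def binary_covariate(name="exposure", irr=2.0, prevalence=0.5):
    beta = {} if irr == 1.0 else {"high": math.log(irr)}
    return Covariate(name, "child", ("ref", "high"),
                     (1 - prevalence, prevalence), beta)


@pytest.fixture(scope="session")
def small_records():
    """Deterministic 3-level cohort with real covariate structure."""
    cfg = SimConfig(n_states=10, neighbourhoods_per_state=4,
                    children_per_neighbourhood=8, seed=101)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit():
    """A small hierarchical MCMC fit shared by summary-statistic tests."""
    cov = (binary_covariate(irr=2.0),)
    cfg = SimConfig(n_states=12, neighbourhoods_per_state=4,
                    children_per_neighbourhood=10, sigma2_state=0.1,
                    sigma2_neigh=0.1, covariates=cov,
                    baseline=BaselineHazard.constant(0.015), horizon=12.0,
                    seed=77)
    records = simulate_dataset(cfg)
    episodes = split_episodes(records, SplitGrid.monthly(12))
    spec = ModelSpec.model(2, mcmc=MCMCSettings(chain_length=1500, burn_in=300,
                                                thinning=3, seed=5))
    draws = fit_mcmc(spec, episodes, cov)
    return draws, episodes


@pytest.fixture
def toy_records():
    """Six hand-placed children for life-table arithmetic."""
    return pd.DataFrame({
        "state_id": 0, "neigh_id": 0, "child_id": np.arange(6),
        "t_obs_months": [0.5, 2.0, 2.5, 5.0, 12.0, 12.0],
        "event": [1, 0, 1, 0, 0, 0],
    })
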