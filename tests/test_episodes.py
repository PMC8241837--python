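import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hiermort import (GridTimeBasis, SplitGrid, fit_poisson_episode_mle,
                      polynomial_basis, split_episodes, time_basis)
from hiermort.simulate import BaselineHazard, SimConfig, simulate_dataset

from conftest import binary_covariate


def _one_child(t, event):
    return pd.DataFrame({"state_id": [0], "neigh_id": [0], "child_id": [0],
                         "t_obs_months": [t], "event": [event]})


def test_event_at_seven_monthly_grid():
    eps = split_episodes(_one_child(7.0, 1), SplitGrid.monthly(12))
    assert len(eps) == 7
    assert eps["d"].tolist() == [0, 0, 0, 0, 0, 0, 1]
    np.testing.assert_allclose(eps["offset"], 0.0)  # log(1) per whole month
    np.testing.assert_allclose(eps["gamma"].sum(), 7.0)


def test_censored_at_sixty_monthly_grid():
    eps = split_episodes(_one_child(60.0, 0), SplitGrid.monthly(60))
    assert len(eps) == 60
    assert eps["d"].sum() == 0
    assert np.exp(eps["offset"]).sum() == pytest.approx(60.0)


def test_event_time_grid_clipping():
    rec = pd.DataFrame({"state_id": 0, "neigh_id": 0, "child_id": [0, 1, 2],
                        "t_obs_months": [3.0, 7.0, 5.0], "event": [1, 1, 0]})
    grid = SplitGrid.from_event_times(rec)
    assert grid.boundaries == (0.0, 3.0, 7.0)
    child = split_episodes(rec, grid)
    censored = child[child["child_id"] == 2]
    np.testing.assert_allclose(censored["a"], [0.0, 3.0])
    np.testing.assert_allclose(censored["b"], [3.0, 5.0])
    np.testing.assert_allclose(censored["offset"],
                               [math.log(3.0), math.log(2.0)])
    assert censored["d"].tolist() == [0, 0]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(
    st.tuples(st.floats(min_value=0.01, max_value=60.0,
                        allow_nan=False, allow_infinity=False),
              st.booleans()),
    min_size=1, max_size=30))
def test_exposure_and_event_conservation(children):
    rec = pd.DataFrame({
        "state_id": 0, "neigh_id": 0, "child_id": np.arange(len(children)),
        "t_obs_months": [t for t, _ in children],
        "event": [int(e) for _, e in children],
    })
    eps = split_episodes(rec, SplitGrid.monthly(60))
    assert eps["gamma"].sum() == pytest.approx(rec["t_obs_months"].sum(),
                                               rel=1e-9)
    assert eps["d"].sum() == rec["event"].sum()
    per_child = eps.groupby("child_id").agg(total=("gamma", "sum"),
                                            events=("d", "sum"),
                                            last_d=("d", "last"))
    np.testing.assert_allclose(per_child["total"],
                               rec.set_index("child_id")["t_obs_months"],
                               rtol=1e-9)
    # the event, when present, sits on the final episode only
    assert (per_child["events"] <= 1).all()
    assert (per_child["events"] == per_child["last_d"]).all()
    assert (eps["gamma"] > 0).all()


def test_follow_up_beyond_grid_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        split_episodes(_one_child(13.0, 0), SplitGrid.monthly(12))


def test_raw_basis_endpoints():
    np.testing.assert_allclose(polynomial_basis(0.0, 4), [1, 0, 0, 0, 0])
    np.testing.assert_allclose(polynomial_basis(1.0, 4), [1, 1, 1, 1, 1])
    # midpoint of [0, 2) over horizon 10 -> s = 0.1
    np.testing.assert_allclose(time_basis((0.0, 2.0), order=2, horizon=10.0),
                               [1.0, 0.1, 0.01])


def test_basis_guards():
    with pytest.raises(ValueError, match="order"):
        polynomial_basis(0.5, 11)
    with pytest.raises(ValueError):
        time_basis((2.0, 1.0))
    with pytest.raises(ValueError, match="negative"):
        time_basis((-3.0, 1.0))


def test_orthogonalized_basis_on_monthly_grid():
    basis = GridTimeBasis(SplitGrid.monthly(60), order=4, orthogonal=True)
    gram = basis.matrix.T @ basis.matrix
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() <= 1e-8


def test_grid_refinement_leaves_fixed_effects_unchanged():
    # with a saturated per-interval baseline, adding cut points between the
    # event times must not move the covariate estimates
    cov = (binary_covariate(irr=2.0),)
    cfg = SimConfig(n_states=3, neighbourhoods_per_state=4,
                    children_per_neighbourhood=15, sigma2_state=0.0,
                    sigma2_neigh=0.0, covariates=cov,
                    baseline=BaselineHazard.constant(0.03), horizon=12.0,
                    seed=29)
    rec = simulate_dataset(cfg)
    coarse = SplitGrid.from_event_times(rec)
    mids = 0.5 * (np.asarray(coarse.boundaries[:-1])
                  + np.asarray(coarse.boundaries[1:]))
    fine = SplitGrid(tuple(sorted({*coarse.boundaries, *mids})))
    beta_coarse = fit_poisson_episode_mle(rec, cov, grid=coarse)
    beta_fine = fit_poisson_episode_mle(rec, cov, grid=fine)
    assert abs(beta_coarse.coef_named()["exposure[high]"]
               - beta_fine.coef_named()["exposure[high]"]) < 1e-6
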