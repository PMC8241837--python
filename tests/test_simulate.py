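import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hiermort import (BaselineHazard, Covariate, SimConfig, fit_cox_oracle,
                      generate_children, read_records, simulate_dataset,
                      simulate_outcomes, write_records)

from conftest import binary_covariate


def _flat_config(n, rate=0.01, horizon=12.0, seed=0, covariates=()):
    """No covariate effects, no clustering: iid exponential death times."""
    return SimConfig(n_states=1, neighbourhoods_per_state=1,
                     children_per_neighbourhood=n, sigma2_state=0.0,
                     sigma2_neigh=0.0, covariates=covariates,
                     baseline=BaselineHazard.constant(rate), horizon=horizon,
                     seed=seed)


def test_generator_is_deterministic(tmp_path):
    cfg = SimConfig(n_states=5, neighbourhoods_per_state=(2, 4),
                    children_per_neighbourhood=(5, 9), seed=33)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    write_records(a, tmp_path / "a.csv")
    write_records(b, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    pd.testing.assert_frame_equal(a, b)


def test_zero_variance_gives_zero_intercepts():
    cfg = SimConfig(n_states=6, neighbourhoods_per_state=3,
                    children_per_neighbourhood=4, sigma2_state=0.0,
                    sigma2_neigh=0.0, seed=2)
    children = generate_children(cfg)
    assert (children["_v_state"] == 0.0).all()
    assert (children["_u_neigh"] == 0.0).all()


def test_state_intercept_variance_recovers_truth():
    # Monte-Carlo check of the generator itself: 500 states
    cfg = SimConfig(n_states=500, neighbourhoods_per_state=1,
                    children_per_neighbourhood=1, sigma2_state=0.2,
                    sigma2_neigh=0.0, covariates=(), seed=9)
    children = generate_children(cfg)
    v = children.drop_duplicates("state_id")["_v_state"].to_numpy()
    assert abs(v.var(ddof=1) - 0.2) < 0.03


def test_constant_hazard_death_probability_closed_form():
    lam, horizon, n = 0.01, 12.0, 20_000
    rec = simulate_dataset(_flat_config(n, rate=lam, horizon=horizon, seed=4))
    p_true = 1.0 - math.exp(-lam * horizon)
    se = math.sqrt(p_true * (1 - p_true) / n)
    assert abs(rec["event"].mean() - p_true) < 3 * se


def test_horizon_censoring_contract():
    rec = simulate_dataset(_flat_config(5000, rate=0.05, horizon=12.0, seed=6))
    assert rec["t_obs_months"].max() <= 12.0
    assert (rec.loc[rec["event"] == 1, "t_obs_months"] < 12.0).all()
    assert set(rec["event"].unique()) <= {0, 1}
    assert (rec["t_obs_months"] > 0).all()


@pytest.mark.parametrize("baseline", [
    BaselineHazard.constant(0.2),
    BaselineHazard.piecewise((0.0, 6.0, 24.0, 60.0), (0.4, 0.15, 0.08)),
])
def test_event_times_match_configured_survival(baseline):
    # with beta = 0 and zero variances, death times are iid with
    # S(t) = exp(-H0(t)); hazards chosen large enough that censoring at the
    # horizon is negligible and the KS test applies to the event times
    cfg = SimConfig(n_states=1, neighbourhoods_per_state=1,
                    children_per_neighbourhood=10_000, sigma2_state=0.0,
                    sigma2_neigh=0.0, covariates=(), baseline=baseline,
                    horizon=60.0, seed=13)
    rec = simulate_dataset(cfg)
    t = rec.loc[rec["event"] == 1, "t_obs_months"].to_numpy()
    assert len(t) > 9900
    cdf = lambda x: 1.0 - baseline.survival(x, 60.0)
    stat, p = stats.kstest(t, cdf)
    assert p > 0.01


def test_raising_log_irr_increases_events():
    counts = []
    for irr in (1.0, 1.5, 2.5, 4.0):
        cov = (binary_covariate(irr=irr),)
        cfg = SimConfig(n_states=5, neighbourhoods_per_state=4,
                        children_per_neighbourhood=40, sigma2_state=0.05,
                        sigma2_neigh=0.05, covariates=cov,
                        baseline=BaselineHazard.constant(0.01), horizon=12.0,
                        seed=21)
        counts.append(simulate_dataset(cfg)["event"].sum())
    assert counts == sorted(counts)
    assert counts[0] < counts[-1]


def test_cox_oracle_recovers_simulated_log_irr():
    cov = (binary_covariate(irr=2.0),)
    cfg = SimConfig(n_states=4, neighbourhoods_per_state=5,
                    children_per_neighbourhood=100, sigma2_state=0.0,
                    sigma2_neigh=0.0, covariates=cov,
                    baseline=BaselineHazard.constant(0.02), horizon=12.0,
                    seed=17)
    rec = simulate_dataset(cfg)
    res = fit_cox_oracle(rec, cov)
    beta_hat = float(res.coef["exposure[high]"])
    se = float(res.se["exposure[high]"])
    assert abs(beta_hat - math.log(2)) < 2 * se


def test_nesting_and_unit_counts():
    cfg = SimConfig(n_states=4, neighbourhoods_per_state=(2, 5),
                    children_per_neighbourhood=3, seed=8)
    children = generate_children(cfg)
    per_state = children.groupby("state_id")["neigh_id"].nunique()
    assert len(per_state) == 4
    assert per_state.between(2, 5).all()
    # every neighbourhood belongs to exactly one state
    assert (children.groupby("neigh_id")["state_id"].nunique() == 1).all()
    assert (children.groupby("neigh_id").size() == 3).all()
    # unit-level covariates are constant within their unit
    assert (children.groupby("neigh_id")["community_illiteracy"].nunique() == 1).all()
    assert (children.groupby("state_id")["rural_pct_band"].nunique() == 1).all()


def test_explicit_per_unit_counts():
    cfg = SimConfig(n_states=3, neighbourhoods_per_state=(2, 1, 3),
                    children_per_neighbourhood=2, seed=1)
    children = generate_children(cfg)
    assert children.groupby("state_id")["neigh_id"].nunique().tolist() == [2, 1, 3]


@pytest.mark.parametrize("kwargs", [
    dict(n_states=0),
    dict(sigma2_state=-0.1),
    dict(horizon=-5),
    dict(baseline=BaselineHazard.piecewise((0.0, 10.0), (-0.1,))),
    dict(baseline=BaselineHazard.piecewise((0.0, 10.0), (0.1,))),  # short of horizon
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)


def test_bad_prevalence_rejected():
    with pytest.raises(ValueError, match="sum"):
        Covariate("x", "child", ("a", "b"), (0.6, 0.5))


def test_outcomes_require_latents(small_records):
    cfg = SimConfig(seed=0)
    with pytest.raises(ValueError, match="latent"):
        simulate_outcomes(small_records, cfg)


def test_config_json_roundtrip():
    cfg = SimConfig(n_states=3, neighbourhoods_per_state=(1, 2, 2),
                    children_per_neighbourhood=4, seed=5)
    assert SimConfig.from_json(cfg.to_json()) == cfg


def test_records_csv_roundtrip(tmp_path, small_records):
    path = tmp_path / "records.csv"
    write_records(small_records, path)
    back = read_records(path)
    assert list(back.columns) == list(small_records.columns)
    np.testing.assert_allclose(back["t_obs_months"], small_records["t_obs_months"])
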