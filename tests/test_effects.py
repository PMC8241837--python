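import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hiermort import (ModelSpec, PosteriorDraws, SIGMA2_LEVEL1, diagnostics,
                      dic, irr_table, mirr, mirr_interval, mirr_inverse, pcv,
                      vpc)


# --------------------------------------------------------------------------
# IRR tables

def _draws_with_beta(beta_matrix, names, covariates=(), spec=None):
    n = len(beta_matrix)
    spec = spec or ModelSpec.model(2)
    return PosteriorDraws(
        beta=np.asarray(beta_matrix, dtype=float), alpha=np.empty((n, 0)),
        u=np.zeros((n, 1)), v=np.zeros((n, 1)),
        sigma2_u=np.full(n, 0.1), sigma2_v=np.full(n, 0.1),
        deviance=np.zeros(n), beta_names=tuple(names), alpha_names=(),
        neigh_ids=np.array([0]), state_ids=np.array([0]), spec=spec,
        covariates=tuple(covariates))


def test_irr_table_constant_chain():
    from conftest import binary_covariate
    cov = binary_covariate(irr=2.0)
    beta = np.column_stack([np.zeros(200), np.full(200, np.log(2.0))])
    draws = _draws_with_beta(beta, ("(Intercept)", "exposure[high]"), (cov,))
    tab = irr_table(draws).set_index("term")
    row = tab.loc["exposure[high]"]
    assert row["irr"] == pytest.approx(2.0)
    assert row["cri_low"] == pytest.approx(2.0)
    assert row["cri_high"] == pytest.approx(2.0)
    ref = tab.loc["exposure[ref]"]
    assert ref["irr"] == 1.0 and bool(ref["reference"])


def test_irr_percentiles_are_exponentiated_order_statistics():
    from conftest import binary_covariate
    cov = binary_covariate(irr=1.0)
    values = np.linspace(-1.0, 1.0, 1000)
    rng = np.random.default_rng(0)
    chain = rng.permutation(values)
    beta = np.column_stack([np.zeros(1000), chain])
    draws = _draws_with_beta(beta, ("(Intercept)", "exposure[high]"), (cov,))
    row = irr_table(draws).set_index("term").loc["exposure[high]"]
    # order-statistic oracle on the sorted chain (linear interpolation):
    # 2.5th percentile index = 0.025 * 999 = 24.975
    s = np.sort(values)
    lo = s[24] + 0.975 * (s[25] - s[24])
    hi = s[974] + 0.025 * (s[975] - s[974])
    assert row["cri_low"] == pytest.approx(np.exp(lo), rel=1e-12)
    assert row["cri_high"] == pytest.approx(np.exp(hi), rel=1e-12)
    assert row["irr"] == pytest.approx(np.exp(np.median(values)), rel=1e-12)


def test_irr_short_chain_warns():
    from conftest import binary_covariate
    cov = binary_covariate(irr=1.0)
    beta = np.zeros((50, 2))
    draws = _draws_with_beta(beta, ("(Intercept)", "exposure[high]"), (cov,))
    with pytest.warns(RuntimeWarning, match="50 kept draws"):
        irr_table(draws)


# --------------------------------------------------------------------------
# VPC / MIRR / PCV against the published random-effects panels

def test_vpc_trivial_and_errors():
    assert vpc(0.0, 0.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        vpc(-0.1, 0.0)
    with pytest.raises(ValueError, match="zero"):
        vpc(0.0, 0.0, sigma2_e=0.0)


def test_mirr_trivial_and_inverse():
    assert mirr(0.0) == 1.0
    with pytest.raises(ValueError):
        mirr(-0.01)
    for s2 in (0.01, 0.19, 0.34, 1.5):
        assert mirr_inverse(mirr(s2)) == pytest.approx(s2, abs=1e-12)


def test_pcv_trivial():
    assert pcv(0.4, 0.4) == 0.0
    assert pcv(0.4, 0.0) == 100.0
    assert pcv(0.2, 0.3) < 0  # reported, not clipped
    with pytest.raises(ValueError):
        pcv(0.0, 0.1)


# Random-effects panels of the infant- and under-five-mortality tables:
# (state sigma2, neigh sigma2, printed state VPC, printed cumulative neigh
# VPC, printed state MIRR, printed neigh MIRR).  Cells excluded where the
# printed value is internally inconsistent with its own printed variance.
INFANT_PANEL = [
    (0.19, 0.19, 5.20, 10.5, 1.52, 1.51),
    (0.07, 0.19, 1.91, 7.34, 1.28, 1.52),
    (0.10, 0.15, 2.88, 7.07, 1.36, 1.44),
    (0.14, 0.04, 3.98, 4.99, 1.42, 1.20),
    (0.06, 0.18, 1.82, 7.00, None, 1.51),   # state MIRR cell inconsistent
]
UNDER5_PANEL = [
    (0.34, 0.21, 8.94, 14.5, 1.75, 1.55),
    (0.14, 0.13, 3.99, 7.58, 1.43, 1.41),
    (0.23, 0.17, 6.28, 10.8, 1.58, 1.48),
    (0.57, 0.21, 14.0, 19.2, 2.06, 1.55),
    (0.14, 0.14, 3.90, 7.74, 1.43, 1.42),
]


@pytest.mark.parametrize("panel", [INFANT_PANEL, UNDER5_PANEL])
def test_printed_table_consistency_sweep(panel):
    for s2v, s2u, vpc_s, vpc_n, mirr_s, mirr_n in panel:
        got_s, got_n = vpc(s2v, s2u)
        assert got_s == pytest.approx(vpc_s, abs=0.5)
        assert got_n == pytest.approx(vpc_n, abs=0.5)
        if mirr_s is not None:
            assert mirr(s2v) == pytest.approx(mirr_s, abs=0.02)
        assert mirr(s2u) == pytest.approx(mirr_n, abs=0.02)


def test_vpc_per_level_option():
    state, neigh = vpc(0.3, 0.2, cumulative_neigh=False)
    total = 0.5 + SIGMA2_LEVEL1
    assert neigh == pytest.approx(100 * 0.2 / total)
    assert state == pytest.approx(100 * 0.3 / total)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(min_value=0.0, max_value=3.0),
       st.floats(min_value=1e-4, max_value=1.0))
def test_mirr_and_vpc_monotone(s2, delta):
    assert mirr(s2 + delta) > mirr(s2)
    lo = vpc(s2, 0.2)
    hi = vpc(s2 + delta, 0.2)
    assert hi[0] > lo[0]
    assert lo[1] >= lo[0] and hi[1] <= 100.0


def test_mirr_interval_from_draws():
    draws = np.array([0.1, 0.2, 0.3])
    point, lo, hi = mirr_interval(draws)
    assert point == pytest.approx(mirr(0.2))
    assert lo <= point <= hi


# --------------------------------------------------------------------------
# DIC

def _dic_fixture(beta_draws, deviances):
    """Intercept-only model on two hand-made episodes of one month each."""
    eps = pd.DataFrame({
        "state_id": [0, 0], "neigh_id": [0, 0], "child_id": [0, 0],
        "k": [0, 1], "a": [0.0, 1.0], "b": [1.0, 2.0],
        "gamma": [1.0, 1.0], "offset": [0.0, 0.0], "d": [0, 1],
    })
    spec = ModelSpec(tiers=(), baseline_order=0, random_effects=False)
    n = len(beta_draws)
    draws = PosteriorDraws(
        beta=np.asarray(beta_draws, dtype=float).reshape(-1, 1),
        alpha=np.empty((n, 0)), u=np.zeros((n, 1)), v=np.zeros((n, 1)),
        sigma2_u=np.full(n, 0.1), sigma2_v=np.full(n, 0.1),
        deviance=np.asarray(deviances, dtype=float),
        beta_names=("(Intercept)",), alpha_names=(),
        neigh_ids=np.array([0]), state_ids=np.array([0]),
        spec=spec, covariates=())
    return draws, eps


def test_dic_constant_chain_has_zero_pd():
    # both episodes have offset 0, so log(mu) = beta and
    # loglik(beta) = d.sum()*beta - 2*exp(beta)
    beta = -0.5
    dev = -2.0 * (1 * beta - 2 * np.exp(beta))
    draws, eps = _dic_fixture([beta] * 5, [dev] * 5)
    res = dic(draws, eps)
    assert res.p_d == pytest.approx(0.0, abs=1e-9)
    assert res.dic == pytest.approx(dev, abs=1e-9)


def test_dic_hand_computed_three_draw_fixture():
    betas = [-1.0, 0.0, 1.0]
    devs = [-2.0 * (b - 2 * np.exp(b)) for b in betas]
    draws, eps = _dic_fixture(betas, devs)
    dbar = float(np.mean(devs))
    dhat = -2.0 * (0.0 - 2 * np.exp(0.0))     # deviance at mean beta = 0
    res = dic(draws, eps)
    assert res.dbar == pytest.approx(dbar, abs=1e-9)
    assert res.p_d == pytest.approx(dbar - dhat, abs=1e-9)
    assert res.dic == pytest.approx(2 * dbar - dhat, abs=1e-9)
    assert res.p_d >= 0


def test_dic_positive_pd_on_fitted_chain(small_fit):
    draws, episodes = small_fit
    res = dic(draws, episodes)
    assert res.p_d >= 0
    assert res.dic >= res.dbar


# --------------------------------------------------------------------------
# diagnostics

def test_diagnostics_iid_chain():
    rng = np.random.default_rng(12)
    out = diagnostics(rng.standard_normal(10_000))
    assert not out["degenerate"]
    assert abs(out["acf"][1]) < 0.03
    assert out["mcse"] == pytest.approx(1 / np.sqrt(10_000), rel=0.25)
    assert len(out["density_x"]) == len(out["density_y"]) == 200


def test_diagnostics_ar1_chain():
    rng = np.random.default_rng(7)
    n, rho = 10_000, 0.9
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for i in range(1, n):
        x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()
    out = diagnostics(x)
    assert out["acf"][1] == pytest.approx(rho, abs=0.03)
    assert out["pacf"][1] == pytest.approx(rho, abs=0.03)


def test_diagnostics_constant_chain_flagged_not_nan():
    out = diagnostics(np.full(500, 3.14))
    assert out["degenerate"]
    for key in ("acf", "pacf", "density_y"):
        assert not np.any(np.isnan(out[key]))
    with pytest.raises(ValueError, match="short"):
        diagnostics([1.0] * 5)
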