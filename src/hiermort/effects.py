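"""Posterior summaries and variance-decomposition statistics.

Covers the quantities reported alongside multilevel Poisson mortality
models: incidence-rate-ratio (IRR) tables with 95% credible intervals,
the variance partition coefficient (VPC) with the latent level-1 variance
pi^2/3, the median incidence rate ratio MIRR = exp(sqrt(2*sigma2) *
Phi^-1(0.75)), the proportional change in variance (PCV, "explained
variation") against the null model, the deviance information criterion
(DIC), and five-way chain diagnostics (trace, density, ACF, PACF, running
quantiles with Monte-Carlo standard errors).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import PosteriorDraws, build_design

__all__ = ["SIGMA2_LEVEL1", "PHI_INV_075", "irr_table", "vpc", "mirr",
           "mirr_inverse", "mirr_interval", "pcv", "dic", "DICResult",
           "diagnostics"]

#: Latent-variable level-1 variance for a binary indicator (pi^2 / 3).
SIGMA2_LEVEL1 = np.pi ** 2 / 3.0

#: 75th percentile of the standard normal.
PHI_INV_075 = float(stats.norm.ppf(0.75))


def irr_table(draws: PosteriorDraws, include_intercept: bool = False) -> pd.DataFrame:
    """Posterior-median IRRs with 95% CrIs, one row per coefficient.

    Summaries are order statistics of the draws, so exponentiation and
    percentile-taking commute: the CrI bounds equal exp(percentiles of the
    beta draws) exactly.  Reference categories of the covariates entering
    the model are inserted with IRR fixed at 1.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior")
    if draws.n_draws < 100:
        warnings.warn(f"only {draws.n_draws} kept draws; credible intervals "
                      "will be unstable", RuntimeWarning)
    rows = []
    by_name = dict(zip(draws.beta_names, draws.beta.T))
    tiers = set(draws.spec.tiers)
    for cov in draws.covariates:
        if cov.tier not in tiers:
            continue
        rows.append({"term": f"{cov.name}[{cov.levels[0]}]", "irr": 1.0,
                     "cri_low": np.nan, "cri_high": np.nan, "reference": True})
        for lev in cov.levels[1:]:
            chain = by_name[f"{cov.name}[{lev}]"]
            rows.append({"term": f"{cov.name}[{lev}]",
                         "irr": float(np.exp(np.median(chain))),
                         "cri_low": float(np.exp(np.percentile(chain, 2.5))),
                         "cri_high": float(np.exp(np.percentile(chain, 97.5))),
                         "reference": False})
    if include_intercept and "(Intercept)" in by_name:
        chain = by_name["(Intercept)"]
        rows.insert(0, {"term": "(Intercept)",
                        "irr": float(np.exp(np.median(chain))),
                        "cri_low": float(np.exp(np.percentile(chain, 2.5))),
                        "cri_high": float(np.exp(np.percentile(chain, 97.5))),
                        "reference": False})
    return pd.DataFrame(rows, columns=["term", "irr", "cri_low", "cri_high",
                                       "reference"])


def vpc(sigma2_state: float, sigma2_neigh: float,
        sigma2_e: float = SIGMA2_LEVEL1,
        cumulative_neigh: bool = True) -> tuple[float, float]:
    """Variance partition coefficients in percent: (state, neighbourhood).

    The state share is sigma2_state / total.  The neighbourhood entry is by
    default cumulative, (sigma2_state + sigma2_neigh) / total -- the
    convention that reproduces published multilevel mortality tables; set
    ``cumulative_neigh=False`` for the per-level share.
    """
    if sigma2_state < 0 or sigma2_neigh < 0 or sigma2_e < 0:
        raise ValueError("variances must be >= 0")
    total = sigma2_state + sigma2_neigh + sigma2_e
    if total == 0:
        raise ValueError("all variance components are zero")
    state = 100.0 * sigma2_state / total
    if cumulative_neigh:
        neigh = 100.0 * (sigma2_state + sigma2_neigh) / total
    else:
        neigh = 100.0 * sigma2_neigh / total
    return state, neigh


def mirr(sigma2: float) -> float:
    """Median incidence rate ratio exp(sqrt(2*sigma2) * Phi^-1(0.75)).

    The median relative rate between two identical children drawn from two
    randomly ordered clusters; 1 when the cluster variance is 0.
    """
    if sigma2 < 0:
        raise ValueError("variance must be >= 0")
    return float(np.exp(np.sqrt(2.0 * sigma2) * PHI_INV_075))


def mirr_inverse(m: float) -> float:
    """Closed-form inverse of :func:`mirr`."""
    if m < 1:
        raise ValueError("MIRR must be >= 1")
    return float((np.log(m) / PHI_INV_075) ** 2 / 2.0)


def mirr_interval(sigma2_draws) -> tuple[float, float, float]:
    """MIRR from the posterior median of sigma2, with a draw-wise 95% CrI."""
    draws = np.asarray(sigma2_draws, dtype=float)
    per_draw = np.exp(np.sqrt(2.0 * draws) * PHI_INV_075)
    return (mirr(float(np.median(draws))),
            float(np.percentile(per_draw, 2.5)),
            float(np.percentile(per_draw, 97.5)))


def pcv(sigma2_null: float, sigma2_model: float) -> float:
    """Explained variation: percent change in a level's variance vs the null
    model.  May be negative; not clipped."""
    if sigma2_null <= 0:
        raise ValueError("null-model variance must be > 0")
    return 100.0 * (sigma2_null - sigma2_model) / sigma2_null


class DICResult(NamedTuple):
    dic: float
    p_d: float
    dbar: float


def dic(draws: PosteriorDraws, episodes: pd.DataFrame) -> DICResult:
    """Deviance information criterion: Dbar + pD, pD = Dbar - D(theta_bar).

    ``theta_bar`` is the posterior mean of all location parameters (fixed
    effects, baseline coefficients and random intercepts)."""
    if draws.n_draws == 0:
        raise ValueError("no stored deviance draws")
    dz = build_design(draws.spec, episodes, draws.covariates)
    beta_m, alpha_m, u_m, v_m = draws.posterior_means()
    hier = draws.spec.random_effects
    dhat = dz.deviance(beta_m, alpha_m, u_m if hier else None,
                       v_m if hier else None)
    dbar = float(draws.deviance.mean())
    p_d = dbar - dhat
    return DICResult(dic=dbar + p_d, p_d=p_d, dbar=dbar)


def diagnostics(chain, nlags: int = 40, density_points: int = 200,
                n_checkpoints: int = 200) -> dict:
    """Five-way MCMC diagnostics as plottable arrays.

    Returns trace, kernel-density (x, y), autocorrelation (biased
    estimator), partial autocorrelation, running 2.5/50/97.5 percent
    quantiles at checkpoints, and a batch-means Monte-Carlo standard error.
    A zero-variance chain is flagged ``degenerate`` instead of emitting
    NaNs.
    """
    from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

    chain = np.asarray(chain, dtype=float).ravel()
    n = len(chain)
    if n < 10:
        raise ValueError("chain too short for diagnostics (need >= 10)")
    out: dict = {"trace": chain, "degenerate": False}
    if np.ptp(chain) == 0.0:
        out["degenerate"] = True
        out.update(density_x=np.array([]), density_y=np.array([]),
                   acf=np.array([]), pacf=np.array([]),
                   checkpoints=np.array([], dtype=int),
                   running_quantiles=np.empty((0, 3)), mcse=0.0)
        return out
    kde = stats.gaussian_kde(chain)
    xs = np.linspace(chain.min(), chain.max(), density_points)
    out["density_x"] = xs
    out["density_y"] = kde(xs)
    lags = min(nlags, n // 2 - 1)
    out["acf"] = sm_acf(chain, nlags=lags, fft=True)
    out["pacf"] = sm_pacf(chain, nlags=min(lags, n // 2 - 2), method="yw")
    checkpoints = np.unique(np.linspace(10, n, min(n_checkpoints, n)).astype(int))
    out["checkpoints"] = checkpoints
    out["running_quantiles"] = np.array(
        [np.percentile(chain[:c], [2.5, 50.0, 97.5]) for c in checkpoints]
    )
    nb = max(2, int(np.sqrt(n)))
    batch = chain[: (n // nb) * nb].reshape(nb, -1).mean(axis=1)
    out["mcse"] = float(batch.std(ddof=1) / np.sqrt(nb))
    return out
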