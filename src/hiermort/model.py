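"""Three-level Bayesian hierarchical Poisson survival model.

The model for episode i of child in neighbourhood j of state k is

    d_ijk ~ Poisson(mu_ijk)
    log(mu_ijk) = x'beta + basis'alpha + U_j + V_k + log(gamma_ijk)

with random intercepts U_j ~ N(0, sigma2_U) per neighbourhood and
V_k ~ N(0, sigma2_V) per state, a smooth (4th-order polynomial) or saturated
per-interval baseline, diffuse Normal(0, 1e6) priors on the location
parameters and Inverse-Gamma(0.001, 0.001) priors on the variances.

Sampling is Metropolis-within-Gibbs: adaptive random-walk Metropolis blocks
for beta and alpha (proposal shaped by the inverse Fisher information at the
IRLS start), vectorised single-site random-walk updates for the U's and V's,
and conjugate inverse-gamma Gibbs draws for the two variances.  Proposal
scales adapt only during burn-in.  The deviance -2*log p(d | theta) is
stored with every kept draw.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .episodes import GridTimeBasis, SplitGrid
from .glm import IRLSResult, poisson_irls
from .simulate import Covariate

__all__ = ["MCMCSettings", "ModelSpec", "PosteriorDraws", "Design", "MCMCError",
           "build_design", "initialize", "fit_mcmc", "fit_poisson_episode_mle",
           "MODEL_TIERS"]

#: Covariate tiers entering Models I-V.
MODEL_TIERS = {
    1: (),
    2: ("child",),
    3: ("neighbourhood",),
    4: ("state",),
    5: ("child", "neighbourhood", "state"),
}


class MCMCError(RuntimeError):
    pass


@dataclass(frozen=True)
class MCMCSettings:
    """Chain controls.  The default is a desk-scale test preset; the long
    preset (chain 50,000 / burn-in 6,000 / thinning 50 / refresh 500) used
    for the published tables is available via :meth:`paper`."""

    chain_length: int = 5000
    burn_in: int = 500
    thinning: int = 5
    refresh: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.chain_length <= self.burn_in:
            raise ValueError("chain_length must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @classmethod
    def paper(cls, seed: int = 0) -> "MCMCSettings":
        return cls(chain_length=50_000, burn_in=6_000, thinning=50,
                   refresh=500, seed=seed)

    @property
    def n_kept(self) -> int:
        return (self.chain_length - self.burn_in) // self.thinning


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate tiers enter, priors, baseline and chain settings."""

    tiers: tuple[str, ...] = ("child", "neighbourhood", "state")
    baseline: str = "polynomial"        # "polynomial" | "interval"
    baseline_order: int = 4
    orthogonal_basis: bool = True
    random_effects: bool = True
    prior_beta_var: float = 1e6
    prior_ig_shape: float = 1e-3
    prior_ig_scale: float = 1e-3
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self):
        bad = set(self.tiers) - {"child", "neighbourhood", "state"}
        if bad:
            raise ValueError(f"unknown tiers {sorted(bad)}")
        if self.baseline not in ("polynomial", "interval"):
            raise ValueError("baseline must be 'polynomial' or 'interval'")
        if self.prior_beta_var <= 0 or self.prior_ig_shape <= 0 or self.prior_ig_scale <= 0:
            raise ValueError("prior parameters must be positive")

    @classmethod
    def model(cls, number: int, **kwargs) -> "ModelSpec":
        """Model I (empty) through Model V (all tiers)."""
        if number not in MODEL_TIERS:
            raise ValueError("model number must be 1..5")
        return cls(tiers=MODEL_TIERS[number], **kwargs)


@dataclass
class Design:
    """Episode-level design arrays shared by the IRLS start and the sampler."""

    X: np.ndarray                 # fixed effects (intercept + dummies)
    B: np.ndarray                 # baseline columns (polynomial or one-hot)
    d: np.ndarray
    offset: np.ndarray
    j_idx: np.ndarray             # neighbourhood codes per episode
    k_idx: np.ndarray             # state codes per episode
    neigh_ids: np.ndarray
    state_ids: np.ndarray
    beta_names: tuple[str, ...]
    alpha_names: tuple[str, ...]

    @property
    def n_neigh(self) -> int:
        return len(self.neigh_ids)

    @property
    def n_state(self) -> int:
        return len(self.state_ids)

    def linear_predictor(self, beta, alpha, u=None, v=None) -> np.ndarray:
        eta = self.X @ beta + self.offset
        if self.B.shape[1]:
            eta = eta + self.B @ alpha
        if u is not None and len(u):
            eta = eta + np.asarray(u)[self.j_idx]
        if v is not None and len(v):
            eta = eta + np.asarray(v)[self.k_idx]
        return eta

    def loglik(self, beta, alpha, u=None, v=None) -> float:
        eta = self.linear_predictor(beta, alpha, u, v)
        return float(self.d @ eta - np.exp(eta).sum())

    def deviance(self, beta, alpha, u=None, v=None) -> float:
        return -2.0 * self.loglik(beta, alpha, u, v)


def _dummy_columns(episodes: pd.DataFrame, covariates, tiers):
    cols, names = [], []
    for cov in covariates:
        if cov.tier not in tiers:
            continue
        values = episodes[cov.name].to_numpy()
        for lev in cov.levels[1:]:
            names.append(f"{cov.name}[{lev}]")
            cols.append((values == lev).astype(float))
    return cols, names


def build_design(spec: ModelSpec, episodes: pd.DataFrame,
                 covariates: tuple[Covariate, ...] = ()) -> Design:
    """Assemble the fixed-effect and baseline design for an episode table."""
    n = len(episodes)
    if n == 0:
        raise ValueError("empty episode table")
    cols, names = _dummy_columns(episodes, covariates, spec.tiers)
    k = episodes["k"].to_numpy(dtype=int)
    if spec.baseline == "polynomial":
        X = np.column_stack([np.ones(n)] + cols)
        beta_names = ("(Intercept)", *names)
        grid_bounds = np.unique(np.concatenate(
            [episodes["a"].to_numpy(), [episodes["b"].to_numpy().max()]]
        ))
        grid = SplitGrid(tuple(grid_bounds)) if grid_bounds[0] == 0.0 else None
        if grid is None or len(grid_bounds) - 1 <= spec.baseline_order:
            # degenerate/coarse grid: fall back to raw midpoint powers
            mids = 0.5 * (episodes["a"].to_numpy() + episodes["b"].to_numpy())
            horizon = float(episodes["b"].to_numpy().max())
            from .episodes import polynomial_basis
            B = polynomial_basis(mids / horizon, spec.baseline_order)[:, 1:]
        else:
            basis = GridTimeBasis(grid, order=spec.baseline_order,
                                  orthogonal=spec.orthogonal_basis)
            B = basis.rows(k)[:, 1:]   # constant direction covered by intercept
        alpha_names = tuple(f"t^{i}" for i in range(1, B.shape[1] + 1))
    else:
        X = (np.column_stack(cols) if cols else np.empty((n, 0)))
        beta_names = tuple(names)
        K = int(k.max()) + 1
        B = np.zeros((n, K))
        B[np.arange(n), k] = 1.0
        alpha_names = tuple(f"interval[{i}]" for i in range(K))
    neigh_ids, j_idx = np.unique(episodes["neigh_id"].to_numpy(), return_inverse=True)
    state_ids, k_idx = np.unique(episodes["state_id"].to_numpy(), return_inverse=True)
    return Design(X=X, B=B, d=episodes["d"].to_numpy(dtype=float),
                  offset=episodes["offset"].to_numpy(dtype=float),
                  j_idx=j_idx, k_idx=k_idx,
                  neigh_ids=neigh_ids, state_ids=state_ids,
                  beta_names=beta_names, alpha_names=alpha_names)


@dataclass
class InitialParams:
    beta: np.ndarray
    alpha: np.ndarray
    cov: np.ndarray     # joint IRLS covariance over (beta, alpha)
    irls: IRLSResult


def initialize(spec: ModelSpec, episodes: pd.DataFrame,
               covariates: tuple[Covariate, ...] = (),
               design: Design | None = None) -> InitialParams:
    """Non-hierarchical Poisson MLE start: fixed effects and baseline at the
    IRLS solution, random effects at 0, variances at 0.1."""
    dz = design if design is not None else build_design(spec, episodes, covariates)
    p = dz.X.shape[1]
    M = np.column_stack([dz.X, dz.B]) if dz.B.shape[1] else dz.X
    ridge = 1e-8 if spec.baseline == "interval" else 0.0
    res = poisson_irls(M, dz.d, dz.offset,
                       names=dz.beta_names + dz.alpha_names, ridge=ridge)
    return InitialParams(beta=res.coef[:p].copy(), alpha=res.coef[p:].copy(),
                         cov=res.cov, irls=res)


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws of every model parameter.

    One row per kept draw; ``u``/``v`` columns are aligned with
    ``neigh_ids``/``state_ids``.  ``deviance`` is -2 log p(d | theta) at the
    draw.  ``meta`` records the seed, acceptance rates and chain settings.
    """

    beta: np.ndarray
    alpha: np.ndarray
    u: np.ndarray
    v: np.ndarray
    sigma2_u: np.ndarray
    sigma2_v: np.ndarray
    deviance: np.ndarray
    beta_names: tuple[str, ...]
    alpha_names: tuple[str, ...]
    neigh_ids: np.ndarray
    state_ids: np.ndarray
    spec: ModelSpec
    covariates: tuple[Covariate, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.deviance)

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for i, name in enumerate(self.beta_names):
            data[f"beta:{name}"] = self.beta[:, i]
        for i, name in enumerate(self.alpha_names):
            data[f"alpha:{name}"] = self.alpha[:, i]
        for i, nid in enumerate(self.neigh_ids):
            data[f"u:{nid}"] = self.u[:, i]
        for i, sid in enumerate(self.state_ids):
            data[f"v:{sid}"] = self.v[:, i]
        data["sigma2_u"] = self.sigma2_u
        data["sigma2_v"] = self.sigma2_v
        data["deviance"] = self.deviance
        return pd.DataFrame(data)

    def write(self, csv_path, meta_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"meta": self.meta,
                           "beta_names": list(self.beta_names),
                           "alpha_names": list(self.alpha_names)}, fh, indent=2)

    def posterior_means(self):
        return (self.beta.mean(axis=0), self.alpha.mean(axis=0),
                self.u.mean(axis=0), self.v.mean(axis=0))


def _sample_inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """One draw from InvGamma(shape, scale): 1/x with x ~ Gamma(shape, 1/scale)."""
    return scale / rng.gamma(shape)


def fit_mcmc(spec: ModelSpec, episodes: pd.DataFrame,
             covariates: tuple[Covariate, ...] = (),
             seed: int | None = None, verbose: bool = False) -> PosteriorDraws:
    """Metropolis-within-Gibbs sampler for the 3-level Poisson model.

    Fully reproducible for a given (spec, data, seed).  Raises
    :class:`MCMCError` naming the offending block if the posterior becomes
    non-finite; warns if a post-adaptation acceptance rate leaves
    [0.05, 0.95].
    """
    settings = spec.mcmc
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    dz = build_design(spec, episodes, covariates)
    init = initialize(spec, episodes, covariates, design=dz)
    beta = init.beta.copy()
    alpha = init.alpha.copy()
    p, q = len(beta), len(alpha)
    J, K = dz.n_neigh, dz.n_state
    hier = spec.random_effects

    def chol_block(sl):
        sub = init.cov[sl, sl]
        sub = 0.5 * (sub + sub.T) + 1e-12 * np.eye(sub.shape[0])
        try:
            return np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return np.diag(np.sqrt(np.clip(np.diag(sub), 1e-12, None)))

    Lb = chol_block(slice(0, p))
    La = chol_block(slice(p, p + q)) if q else None
    log_sb = math.log(2.38 / math.sqrt(max(p, 1)))
    log_sa = math.log(2.38 / math.sqrt(max(q, 1)))
    u = np.zeros(J)
    v = np.zeros(K)
    s2u = s2v = 0.1
    u_log_scales = np.full(J, math.log(0.5))
    v_log_scales = np.full(K, math.log(0.5))

    D_j = np.bincount(dz.j_idx, weights=dz.d, minlength=J)
    D_k = np.bincount(dz.k_idx, weights=dz.d, minlength=K)
    prior_prec = 1.0 / spec.prior_beta_var
    a0, b0 = spec.prior_ig_shape, spec.prior_ig_scale

    eta = dz.linear_predictor(beta, alpha, u if hier else None, v if hier else None)
    mu = np.exp(eta)
    ll = float(dz.d @ eta - mu.sum())

    n_keep = settings.n_kept
    out_beta = np.empty((n_keep, p))
    out_alpha = np.empty((n_keep, q))
    out_u = np.empty((n_keep, J))
    out_v = np.empty((n_keep, K))
    out_s2u = np.empty(n_keep)
    out_s2v = np.empty(n_keep)
    out_dev = np.empty(n_keep)

    acc = {"beta": [0, 0], "alpha": [0, 0], "u": [0, 0], "v": [0, 0]}
    kept = 0

    def check_finite(value, block):
        if not np.isfinite(value):
            raise MCMCError(f"divergent chain: non-finite posterior in block {block!r}")

    for it in range(1, settings.chain_length + 1):
        adapting = it <= settings.burn_in
        gamma_t = min(0.25, 2.0 * it ** -0.6)

        # ---- beta block --------------------------------------------------
        prop = beta + math.exp(log_sb) * (Lb @ rng.standard_normal(p))
        delta_eta = dz.X @ (prop - beta)
        eta_p = eta + delta_eta
        with np.errstate(over="ignore"):
            mu_p = np.exp(eta_p)
        ll_p = float(dz.d @ eta_p - mu_p.sum())
        logr = (ll_p - ll
                - 0.5 * prior_prec * (prop @ prop - beta @ beta))
        check_finite(ll, "beta")
        accepted = math.log(rng.uniform()) < logr
        if accepted:
            beta, eta, mu, ll = prop, eta_p, mu_p, ll_p
        acc["beta"][0] += accepted
        acc["beta"][1] += 1
        if adapting:
            log_sb += gamma_t * (accepted - 0.234)

        # ---- alpha block -------------------------------------------------
        if q:
            prop = alpha + math.exp(log_sa) * (La @ rng.standard_normal(q))
            eta_p = eta + dz.B @ (prop - alpha)
            with np.errstate(over="ignore"):
                mu_p = np.exp(eta_p)
            ll_p = float(dz.d @ eta_p - mu_p.sum())
            logr = (ll_p - ll
                    - 0.5 * prior_prec * (prop @ prop - alpha @ alpha))
            check_finite(ll, "alpha")
            accepted = math.log(rng.uniform()) < logr
            if accepted:
                alpha, eta, mu, ll = prop, eta_p, mu_p, ll_p
            acc["alpha"][0] += accepted
            acc["alpha"][1] += 1
            if adapting:
                log_sa += gamma_t * (accepted - 0.234)

        if hier:
            # ---- neighbourhood intercepts (vectorised single-site MH) ----
            S_j = np.bincount(dz.j_idx, weights=mu, minlength=J) * np.exp(-u)
            prop_u = u + np.exp(u_log_scales) * rng.standard_normal(J)
            dll = (D_j * (prop_u - u)
                   - S_j * (np.exp(prop_u) - np.exp(u))
                   - (prop_u ** 2 - u ** 2) / (2.0 * s2u))
            check_finite(float(dll.sum()), "u")
            acc_u = np.log(rng.uniform(size=J)) < dll
            if acc_u.any():
                step = np.where(acc_u, prop_u - u, 0.0)
                u = u + step
                eta = eta + step[dz.j_idx]
                mu = mu * np.exp(step[dz.j_idx])
            acc["u"][0] += int(acc_u.sum())
            acc["u"][1] += J
            if adapting:
                u_log_scales += gamma_t * (acc_u - 0.44)

            # ---- state intercepts ---------------------------------------
            S_k = np.bincount(dz.k_idx, weights=mu, minlength=K) * np.exp(-v)
            prop_v = v + np.exp(v_log_scales) * rng.standard_normal(K)
            dll = (D_k * (prop_v - v)
                   - S_k * (np.exp(prop_v) - np.exp(v))
                   - (prop_v ** 2 - v ** 2) / (2.0 * s2v))
            check_finite(float(dll.sum()), "v")
            acc_v = np.log(rng.uniform(size=K)) < dll
            if acc_v.any():
                step = np.where(acc_v, prop_v - v, 0.0)
                v = v + step
                eta = eta + step[dz.k_idx]
                mu = mu * np.exp(step[dz.k_idx])
            acc["v"][0] += int(acc_v.sum())
            acc["v"][1] += K
            if adapting:
                v_log_scales += gamma_t * (acc_v - 0.44)

            # ---- conjugate variance draws -------------------------------
            s2u = _sample_inv_gamma(rng, a0 + 0.5 * J, b0 + 0.5 * float(u @ u))
            s2v = _sample_inv_gamma(rng, a0 + 0.5 * K, b0 + 0.5 * float(v @ v))
            ll = float(dz.d @ eta - mu.sum())

        if it % settings.refresh == 0:
            # guard against numerical drift of the cached linear predictor
            eta = dz.linear_predictor(beta, alpha, u if hier else None,
                                      v if hier else None)
            mu = np.exp(eta)
            ll = float(dz.d @ eta - mu.sum())
            if verbose:
                print(f"iteration {it}/{settings.chain_length}  loglik {ll:.2f}")

        if it > settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
            out_beta[kept] = beta
            out_alpha[kept] = alpha
            out_u[kept] = u
            out_v[kept] = v
            out_s2u[kept] = s2u
            out_s2v[kept] = s2v
            out_dev[kept] = -2.0 * ll
            kept += 1

    rates = {k: (c / t if t else float("nan")) for k, (c, t) in acc.items()}
    for blk in ("beta", "alpha") if q else ("beta",):
        r = rates[blk]
        if np.isfinite(r) and not (0.05 <= r <= 0.95):
            warnings.warn(
                f"{blk} block acceptance rate {r:.3f} outside [0.05, 0.95] "
                "after adaptation", RuntimeWarning)
    meta = {
        "seed": int(settings.seed if seed is None else seed),
        "chain_length": settings.chain_length, "burn_in": settings.burn_in,
        "thinning": settings.thinning, "acceptance_rates": rates,
        "random_effects": hier, "tiers": list(spec.tiers),
    }
    return PosteriorDraws(beta=out_beta[:kept], alpha=out_alpha[:kept],
                          u=out_u[:kept], v=out_v[:kept],
                          sigma2_u=out_s2u[:kept], sigma2_v=out_s2v[:kept],
                          deviance=out_dev[:kept],
                          beta_names=dz.beta_names, alpha_names=dz.alpha_names,
                          neigh_ids=dz.neigh_ids, state_ids=dz.state_ids,
                          spec=spec, covariates=tuple(covariates), meta=meta)


def fit_poisson_episode_mle(records: pd.DataFrame,
                            covariates: tuple[Covariate, ...],
                            grid: SplitGrid | None = None,
                            baseline: str = "interval") -> IRLSResult:
    """Episode-split Poisson MLE of the covariate effects (no random effects).

    With the default unique-event-times grid and the saturated per-interval
    baseline this reproduces the Cox partial-likelihood estimates with
    Breslow tie handling.  Intervals containing no events are dropped before
    fitting: their saturated baseline rates have no finite MLE and they
    carry no information about the covariate effects.
    """
    from .episodes import split_episodes

    if grid is None:
        grid = SplitGrid.from_event_times(records)
    eps = split_episodes(records, grid)
    spec = ModelSpec(tiers=("child", "neighbourhood", "state"),
                     baseline=baseline, random_effects=False)
    if baseline == "interval":
        with_events = set(eps.loc[eps["d"] == 1, "k"].unique())
        eps = eps[eps["k"].isin(with_events)].copy()
        # re-code interval indices densely so the one-hot design is full rank
        codes = {old: new for new, old in enumerate(sorted(with_events))}
        eps["k"] = eps["k"].map(codes)
    dz = build_design(spec, eps, covariates)
    M = np.column_stack([dz.X, dz.B]) if dz.B.shape[1] else dz.X
    return poisson_irls(M, dz.d, dz.offset, names=dz.beta_names + dz.alpha_names)
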