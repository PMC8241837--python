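# Methods

## Model

For child *i* in neighbourhood *j* in state *k*, the hazard of death is

    h_ijk(t) = h0(t) · exp(x'β + U_jk + V_k),
    U_jk ~ N(0, σ²_U),  V_k ~ N(0, σ²_V).

Follow-up is expanded into episodes (one row per child × time interval
entered), each carrying an event indicator d, time at risk γ and offset
log γ. Conditional on the random effects the piecewise-exponential
likelihood factorises into independent Poisson terms

    d ~ Poisson(μ),  log μ = x'β + λ(t) + U_jk + V_k + log γ,

which is the model actually fitted. The indicator d is not Poisson
marginally; the construction only borrows the Poisson likelihood's form.
Two baselines λ(t) are available:

- **polynomial** (default): a 4th-order polynomial in scaled time
  s = midpoint/horizon, orthogonalised over the grid by QR with a fixed
  sign convention. Raw powers of s on [0, 60] months are nearly collinear;
  the orthogonal basis keeps the information matrix well conditioned
  without changing the fitted curve. The constant direction is carried by
  the intercept.
- **interval**: one rate per grid interval (saturated). Combined with the
  unique-event-times grid this makes the Poisson MLE of β identical to the
  Cox partial-likelihood MLE with Breslow tie handling; it exists mainly
  for that equivalence and its tests. Intervals without events are dropped
  before the MLE fit — their saturated rates have no finite MLE and they
  carry no information about β.

Episode intervals are half-open [a, b); an event at an interior boundary
belongs to the interval it closes, so the event always sits on a child's
final episode and per-child exposure sums to t_obs exactly.

## Priors, sampler, initialisation

The analysis is Bayesian with the diffuse defaults of the multilevel
software tradition this model family comes from: fixed effects and baseline
coefficients N(0, 10⁶); variances InvGamma(0.001, 0.001). Models I–V enter
covariates by tier: none / individual / neighbourhood / state / all.

Sampling is Metropolis-within-Gibbs:

- β and α (baseline) blocks: random-walk Metropolis with proposal
  covariance from the inverse Fisher information at the IRLS start, scalar
  scale adapted towards acceptance 0.234 during burn-in only;
- U and V: vectorised single-site random walks (sites are conditionally
  independent given the other blocks), per-site scales adapted towards
  0.44 during burn-in;
- σ²_U, σ²_V: conjugate inverse-gamma Gibbs draws
  InvGamma(a + J/2, b + ΣU²/2).

Initialisation is deterministic: the non-hierarchical Poisson MLE by an
in-package IRLS (with step halving, so the deviance trace is
non-increasing), random effects at 0, variances at 0.1. The cached linear
predictor is recomputed from scratch at every refresh interval to prevent
numerical drift. The deviance −2 log p(d | θ) is stored with every kept
draw; DIC uses p_D = D̄ − D(θ̄) with θ̄ the posterior mean of all location
parameters.

Chain defaults: the desk-scale preset is 5,000 iterations / 500 burn-in /
thinning 5, which the parameter-recovery tests show is sufficient for the
cohort sizes used there; `MCMCSettings.paper()` gives the long preset
(50,000 / 6,000 / 50, refresh 500) matching the published run
configuration. Reproducibility is exact for fixed (spec, data, seed).
Acceptance rates outside [0.05, 0.95] after adaptation raise a warning;
a non-finite posterior aborts naming the offending block.

## Variance decomposition

- **VPC**: level share of total latent variance with level-1 variance
  π²/3 ≈ 3.290 (the latent-variable convention for a binary indicator).
  The neighbourhood row is *cumulative*, (σ²_U + σ²_V)/total, by default —
  the convention consistent with the published null-model panels — with the
  per-level share available via `cumulative_neigh=False`.
- **MIRR**: exp(√(2σ²)·Φ⁻¹(0.75)); point estimate from the posterior
  median of σ², credible interval by applying the formula draw-wise
  (a monotone transform, so the interval is the transformed σ² interval).
- **PCV** ("explained variation"): (σ²_null − σ²_model)/σ²_null × 100 per
  level, against Model I posterior medians; negative values are reported,
  not clipped.
- IRR summaries are order statistics of the β draws, exponentiated — the
  credible bounds equal exp(percentiles of β) exactly.

## Life tables

Rates per 1000 livebirths use the actuarial convention: per age segment,
q = deaths / (entrants − censored/2); the window rate is
1000·(1 − Π(1 − q)) over segments below 12 (INMR) or 60 (U5MR) months.
The default grid is the DHS-style segmentation 0–1–3–6–12–24–36–48–60
months; the grid is configurable because the published analysis names only
the technique, not its segments. A child censored exactly at a boundary
has completed the closing segment, so with no censoring inside the window
the rate reduces exactly to the simple proportion dying. An optional
per-record weight column multiplies deaths and exposures; rates are
unweighted by default (survey-weight construction is out of scope).

## Synthetic data

The generator emulates the structure of a DHS child recode: 37 states,
clusters nested in states, one row per child with follow-up in months,
death indicator and categorical covariates at the child, neighbourhood and
state tiers (unit-tier covariates drawn once per unit and copied to its
children). Defaults: 37 × 10 × 15 ≈ 5,550 children; random-intercept
variances 0.19/0.19 (the null-model posteriors of the infant-mortality
analysis); covariate prevalences echoing the survey's descriptive
distribution with generating IRRs in the 1.2–2.5 range; and a declining
piecewise baseline hazard calibrated once so the marginal rates land near
the national ≈70 (INMR) and ≈131 (U5MR) per 1000. The full
33,924/1,389/37 shape is available as the `paper-shape` preset with
deterministic per-unit counts summing to the published totals.

Death times are drawn by exact inversion of the cumulative hazard
(constant and piecewise baselines) or by thinning (polynomial log-hazard),
in continuous time, so exact zeros and tied event times have probability
zero. Administrative censoring at the horizon (12 or 60 months) is always
applied; uniform interview-age censoring on (0, 60) is available but off
by default so closed-form checks stay exact — the survey's own convention
(censoring at current age vs 59 months) is not stated, and both are
supported via the flag.

What the generator does **not** emulate: survey weights and the wealth
index's asset-PCA construction (wealth is simulated directly as a
tertile), informative censoring, within-family correlation beyond the
cluster intercepts, covariate missingness, and spatial correlation between
neighbouring clusters. Passing tests therefore validate the estimators
under the model's own assumptions, not robustness to those survey
features.

## Numerical and design choices

- Collinearity screen: Pearson correlations over ordinally coded
  categoricals (declared level order, otherwise sorted labels), flagging
  |r| ≥ 0.6 by default; constant columns are reported degenerate rather
  than paired. Rural-percentage banding rounds to one decimal before
  applying the 33.3/66.7 band edges, making the banding exhaustive and
  mutually exclusive on [0, 100].
- Random slopes are deliberately absent: the fitted models are
  random-intercept only.
- Degenerate clusters (a single child) are allowed; their intercepts are
  still sampled and shrink to zero under the prior.
- The IRLS initialiser declares convergence at score max-norm < 1e-8 and
  reports the gradient norm on failure; a tiny ridge (1e-8) stabilises the
  saturated-baseline start only.
- Problem sizes in the test suite are desk-scale by design (hundreds to
  ~10,000 children, reduced chains); the same code paths scale to the full
  survey shape with the long chain preset.

## Known limitations

- The intercept and the mean of the state intercepts are weakly
  identified (as in any random-intercept model with diffuse priors);
  mixing of V is adequate at the tested scales but slow chains should use
  the long preset.
- MIRR credible intervals are transformed variance intervals, not profile
  intervals.
- DIC uses the plug-in posterior mean of location parameters; for strongly
  skewed posteriors p_D can be unstable (it is checked non-negative on the
  packaged fixtures, not in general).
- The event-times grid treats tied event times as one cut point; the Cox
  equivalence then holds against Breslow tie handling specifically.
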