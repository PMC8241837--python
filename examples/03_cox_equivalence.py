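"""Episode-split Poisson regression reproduces the Cox model.

Splitting each child's follow-up at every unique event time, attaching
offset log(time-at-risk) and giving each interval its own baseline rate
makes the Poisson MLE of the covariate effects identical to the Cox
partial-likelihood estimates (Breslow tie handling).  This equivalence is
what licenses fitting censored survival data with a hierarchical Poisson
model.
"""

import math

from hiermort import (BaselineHazard, Covariate, SimConfig, fit_cox_oracle,
                      fit_poisson_episode_mle, simulate_dataset)

cov = (Covariate("exposure", "child", ("ref", "high"), (0.5, 0.5),
                 {"high": math.log(2.0)}),)
config = SimConfig(n_states=4, neighbourhoods_per_state=5,
                   children_per_neighbourhood=10, sigma2_state=0.0,
                   sigma2_neigh=0.0, covariates=cov,
                   baseline=BaselineHazard.constant(0.025), horizon=12.0,
                   seed=40)
records = simulate_dataset(config)
print(f"{len(records)} children, {int(records['event'].sum())} deaths; "
      f"true log-IRR {math.log(2.0):.4f}")

cox = fit_cox_oracle(records, cov)
pois = fit_poisson_episode_mle(records, cov)

b_cox = float(cox.coef["exposure[high]"])
b_poi = pois.coef_named()["exposure[high]"]
print(f"Cox partial likelihood : {b_cox:.6f}")
print(f"episode-split Poisson  : {b_poi:.6f}")
print(f"absolute difference    : {abs(b_cox - b_poi):.2e}")
print("\nThe two estimates agree to numerical precision: the piecewise")
print("exponential likelihood and the partial likelihood share a maximiser.")
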