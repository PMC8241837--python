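"""Run the full pipeline: simulate, screen, rates, fit Models I and V.

Model I is the empty (random-intercepts only) reference; Model V adds the
covariates.  The run bundle lands in ./scratch_pipeline_demo: rate tables,
collinearity report, per-model IRR panels, and a random-effects summary
with variance, VPC, MIRR, explained variation and DIC per model.
"""

import math

import pandas as pd

from hiermort import RunConfig, run
from hiermort.model import MCMCSettings
from hiermort.simulate import BaselineHazard, Covariate, SimConfig

cov = (Covariate("exposure", "child", ("ref", "high"), (0.5, 0.5),
                 {"high": math.log(2.5)}),)
sim = SimConfig(n_states=8, neighbourhoods_per_state=4,
                children_per_neighbourhood=8, sigma2_state=0.1,
                sigma2_neigh=0.1, covariates=cov,
                baseline=BaselineHazard.constant(0.02), horizon=12.0, seed=11)
config = RunConfig(sim=sim, outcomes=("inm",), models=(1, 5),
                   mcmc=MCMCSettings(chain_length=800, burn_in=200,
                                     thinning=3, seed=3),
                   outdir="scratch_pipeline_demo", seed=3)

manifest = run(config)
print(f"pipeline finished in {manifest['seconds_total']}s; "
      f"stages: {manifest['stages']}")

summary = pd.read_csv("scratch_pipeline_demo/model_summary_inm.csv")
cols = ["model", "sigma2_state", "sigma2_neigh", "vpc_state", "vpc_neigh",
        "mirr_state", "mirr_neigh", "pcv_state", "dic"]
print("\nrandom-effects summary:")
print(summary[cols].round(3).to_string(index=False))
print("\nModel V should show a lower DIC than the empty model because the")
print("data were generated with a strong individual-level effect.")
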