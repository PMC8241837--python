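"""Simulate a three-level child-survival cohort and look at its structure.

Children are nested in neighbourhoods (survey clusters) nested in states,
with categorical covariates at each tier and Gaussian random intercepts on
the log-hazard scale.  The default configuration is desk-scale (37 states x
10 clusters x 15 children) with marginal mortality near the national
rates of roughly 70 (infant) and 131 (under-five) per 1000 livebirths.
"""

from hiermort import SimConfig, simulate_dataset

config = SimConfig(seed=1)
records = simulate_dataset(config)

print(f"children: {len(records)}, clusters: {records['neigh_id'].nunique()}, "
      f"states: {records['state_id'].nunique()}")
print(f"deaths observed: {int(records['event'].sum())} "
      f"({100 * records['event'].mean():.1f}% of the cohort)")
print("\nfirst three records:")
print(records.head(3).to_string(index=False))
print("\nEach row is one child: follow-up time in months, a death indicator,")
print("and covariates that are constant within the child's cluster or state")
print("for the neighbourhood- and state-tier variables.")
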