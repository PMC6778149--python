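"""Thin occurrences and select uncorrelated climate predictors.

Occurrence records are spatially thinned to one point per minimum
separation distance, climate values are extracted at the occupied cells,
and predictors are screened in two passes: correlation grouping
(|r| > 0.5 joins two variables) followed by variance-inflation-factor
filtering on the group representatives.
"""

import nichedyn as nd

spec = nd.make_scenario("identical", seed=7)
stack = nd.make_climate(spec, "A")
occ = nd.sample_scenario(spec)["A"]

thinned = nd.thin_occurrences(occ, min_sep=0.05)
print(f"thinning at 0.05 deg: {len(occ)} -> {len(thinned)} records")

env = nd.extract_env(thinned, stack)
print(f"extracted climate at {len(env)} records, "
      f"variables: {env.variables}")

groups = nd.correlation_groups(env, threshold=0.5)
print(f"\ncorrelation groups at |r| > 0.5: {groups}")

selected, vif_table, _ = nd.select_predictors(env, r_threshold=0.5,
                                              vif_cutoff=5.0)
print("\nVIF screening of the group representatives:")
print(vif_table.to_string(index=False))
print(f"\nselected predictors: {selected}")
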