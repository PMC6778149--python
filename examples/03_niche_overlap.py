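"""Compare two ranges' climatic niches in a shared environmental space.

A PCA is calibrated on the pooled background climates of both ranges
("PCA-env"), occurrence and background densities are kernel-smoothed on
its first two axes, and the ranges are compared with Schoener's D, the
equivalency and similarity permutation tests, and the niche-dynamics
indices expansion / stability / unfilling.
"""

import nichedyn as nd

spec = nd.make_scenario("shifted", seed=3)
stacks = {h.range_label: nd.make_climate(spec, h.region) for h in spec.niches}
occs = nd.sample_scenario(spec)

bkgs = [nd.build_background(occs[k], stacks[k], buffer_deg=0.3)
        for k in stacks]
space = nd.pca_env(bkgs, grid_resolution=200)
print("PCA-env explained variance:",
      [f"{f:.1%}" for f in space.explained_variance])

scores, dens = {}, {}
for k in stacks:
    scores[k] = space.transform(nd.extract_env(occs[k], stacks[k]).values)
    dens[k] = nd.occurrence_density(scores[k], space.background_scores[k],
                                    space, range_label=k)

cmp = nd.compare_pair("A", "B", scores, dens, space, n_reps=100, seed=0)
print(f"\nSchoener's D (A vs B):        {cmp.D_obs:.3f}")
print(f"equivalency test p (lower):   {cmp.equivalency_p_lower:.3f}"
      "   (small p -> niches less equivalent than chance)")
print(f"similarity test p (greater):  {cmp.similarity_p_greater:.3f}"
      "   (small p -> more similar than a random placement)")
print(f"\nniche dynamics (A -> B):")
print(f"  expansion = {cmp.expansion:.3f}"
      f"   stability = {cmp.stability:.3f}"
      f"   unfilling = {cmp.unfilling:.3f}")
print(f"  expansion ecologically relevant (> {nd.RELEVANCE_THRESHOLD}): "
      f"{cmp.expansion_relevant}")
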