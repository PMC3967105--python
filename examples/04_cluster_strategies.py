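"""Cluster production targets by the Jaccard similarity of their
knockout strategies.

Screens four randomized toy networks, takes each one's best OptKnock
knockout set as that target's strategy, and builds the UPGMA dendrogram
on Jaccard distance 1 - J.  Targets whose strains share deletions merge
low in the tree.
"""

import fastpros as fp

env = fp.toy_environment()
strategies = {}
for seed in (0, 1, 2, 3):
    model = fp.make_random_toy(fp.ToyModelSpec(seed=seed))
    fp.apply_environment(model, env)
    units = fp.default_toy_units(model)
    refined = fp.fastpros_then_optknock(model, env, "T_c", units, k_list=[3])
    best = refined[3]
    if best.status == "optimal" and best.knockout_units:
        strategies[f"target_{seed}"] = set(best.knockout_units)
        print(f"target_{seed}: knockouts {sorted(best.knockout_units)} "
              f"({best.yield_fraction_tmy:.2f} of TMY)")

result = fp.cluster_targets(strategies, method="average", cut_height=0.5)
print("\nsimilarity matrix (Jaccard):")
print(result.similarity.to_dataframe().round(2))
print("\nnewick:", result.newick)
print("clusters at distance 0.5:", result.labels)
# label = cluster id; targets sharing a label rely on overlapping
# knockout strategies.
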