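"""Model reduction: blocked-reaction removal, pathway lumping, units.

Draws a randomized toy network containing a linear two-step pathway and
a dead-end reaction, then shows how reduction removes the dead end,
lumps the unbranched pathway into one reaction (recording flux scale
factors), and partitions reactions into knockout units.
"""

import fastpros as fp

model = fp.make_random_toy(fp.ToyModelSpec(seed=3))
env = fp.toy_environment()
fp.apply_environment(model, env)

print(f"original reactions : {sorted(r.id for r in model.reactions)}")
reduced = fp.reduce_model(model, env)
print(f"reduced reactions  : {sorted(r.id for r in reduced.model.reactions)}")
print(f"removed as blocked : {reduced.map.removed_blocked}")
for lump, members in reduced.map.lumped_to_original.items():
    print(f"lumped {lump}: members {members}")
    # scale factors convert the lumped flux back to each member's flux

g0 = fp.maximize_biomass(model, env).objective_value
g1 = fp.maximize_biomass(reduced.model, env).objective_value
print(f"biomass optimum before/after reduction: {g0:.6f} / {g1:.6f}")

print("knockout units (knockable marked *):")
for unit in reduced.units:
    mark = "*" if unit.knockable else " "
    print(f" {mark} {unit.unit_id}: {sorted(unit.member_reactions)}")
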