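"""Score knockouts by shadow price and run the beam-search screen.

Builds the hand-solvable TOY1 network (substrate A -> biomass, with an
NADH by-product that must be vented or respired, and a target T that
consumes both A and NADH), scores the wild type and the vent knockout,
then screens for all candidate knockout sets.
"""

import fastpros as fp

model = fp.make_toy1()
env = fp.toy_environment()
fp.apply_environment(model, env)

wt = fp.shadow_price_score(model, env, "T_c")
ko = fp.shadow_price_score(model, env, "T_c", ["R2"])
print(f"wild-type score      : {wt.f_target:+.3f} ({wt.classification})")
print(f"vent knockout score  : {ko.f_target:+.3f} ({ko.classification})")
# A negative score means each unit of forced T production costs that much
# growth; a positive score means T has become a by-product of growth.

units = fp.default_toy_units(model)
result = fp.screen(model, env, "T_c", units)
print(f"candidate knockout sets ({len(result.candidates)}):")
for rec in result.candidates:
    print(f"  {sorted(rec.knockouts)}  score {rec.f_target:+.3f}")
print(f"minimum knockouts for production: {result.min_knockouts}")
print(f"LP evaluations: {result.evaluations}")
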