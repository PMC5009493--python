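"""Classify the metabolic interaction between two species.

Builds a cross-feeding pair (species A turns substrate S into biomass plus a
byproduct P; species B can only grow on P), merges the two models through a
shared lumen compartment, estimates the four growth rates under a diet
supplying only S, and assigns the interaction type.
"""

from pairmint import build_community, classify, community_growth, make_toy_pair

model_a, model_b, diet, _ = make_toy_pair("commensalism")
community = build_community(model_a, model_b, tag_a="A", tag_b="B")
growth = community_growth(community, diet)
record = classify(growth)

print(f"diet: {diet.fluxes}  (max uptake, mmol/gDW/hr)")
print(f"A alone {growth.g_a_alone:.2f} /hr, together {growth.g_a_together:.2f} /hr")
print(f"B alone {growth.g_b_alone:.2f} /hr, together {growth.g_b_together:.2f} /hr")
print(f"interaction: {record.type_label} ({record.polarity})")

# B cannot grow without A's byproduct (alone 0.00, together 10.00): an
# obligate commensal gain for B, no effect on A -> commensalism, positive.
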