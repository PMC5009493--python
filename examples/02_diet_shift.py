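"""Shift nutrient availability and watch community growth respond.

Takes the competition pair (two species sharing one substrate) and solves it
under a diet, its ten-fold reduction and its hundred-fold reduction.  The
joint community growth can only shrink as the diet is scaled down (each
scaled LP is a restriction of the previous one), while the interaction type
stays competitive at every scale.
"""

from pairmint import (
    build_community,
    classify,
    community_growth,
    make_toy_pair,
    scale_diet,
)

model_a, model_b, diet, _ = make_toy_pair("competition")
community = build_community(model_a, model_b)

for factor in (1.0, 0.1, 0.01):
    scaled = scale_diet(diet, factor)
    growth = community_growth(community, scaled)
    record = classify(growth)
    total = growth.g_a_together + growth.g_b_together
    print(
        f"diet {scaled.name:20s} joint growth {total:6.2f} /hr "
        f"(split {growth.g_a_together:.2f}/{growth.g_b_together:.2f})  "
        f"type: {record.type_label}"
    )

# The fair degeneracy resolution splits the contested substrate evenly, so
# both competitors lose exactly half of their isolated growth at any scale.
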