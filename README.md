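# pairmint

Predict pairwise **metabolic interactions** among the members of a microbial
community — from an OTU association network and 16S rDNA sequences, through
two-species community metabolic models and flux balance analysis under
defined diets, to a typed, color-coded interaction network.

16S surveys tell us which taxa co-occur, but correlation says nothing about
*why*: are two organisms competing for a substrate, cross-feeding, or simply
indifferent? pairmint bridges that gap mechanistically. It is built for
microbiome researchers who have (1) an OTU association table, (2) the OTU
16S sequences, (3) a reference FASTA of genome 16S sequences, and (4)
genome-scale metabolic models (SBML L3 + FBC v2, e.g. automated
reconstructions) for those genomes.

## The method

For each associated pair of species, the two single-species models are merged
through a fictitious shared extracellular compartment (the *lumen*, `u`):
every species exchange reaction on an extracellular metabolite M is replaced
by a reversible transport `M_e ↔ M_u`, and one community exchange
`EX_M_u: M_u → ∅` per lumen metabolite becomes the model's only boundary. A
*diet* d assigns each lumen metabolite a maximum uptake flux (mmol/gDW/hr)
by setting the community exchange bounds to `[-d(M), 1000]` (uptake is
negative flux; metabolites not in the diet can only be secreted).

Four growth rates per pair come from flux balance analysis
(max wᵀv s.t. S·v = 0, lb ≤ v ≤ ub):

* **together** — maximize the sum of both biomass fluxes v_A + v_B. When the
  optimum is degenerate (pure competition pins down only the sum), the
  default *fair* mode fixes the sum at its optimum and maximizes
  min(v_A, v_B); `degeneracy="vertex"` returns the raw solver vertex instead.
* **alone** — the same diet-constrained community with all of the partner's
  reactions silenced (bounds zeroed), maximizing the focal biomass.

Each species' effect is the percent change δ = 100·(g_together −
g_alone)/g_alone (an `OBLIGATE_GAIN` sentinel when g_alone = 0 <
g_together), reduced to a sign with a strict 10 % rule (δ > +10 → `+`,
δ < −10 → `−`, else `0`). The sign pair maps to the classical types —
mutualism (+,+), commensalism (+,0), parasitism (+,−), competition (−,−),
amensalism (−,0), neutralism (0,0) — with polarity positive for
{mutualism, commensalism}, negative for {parasitism, amensalism,
competition}, none for neutralism.

OTUs are tied to genomes by best local alignment (Smith–Waterman, match +2,
mismatch −3, gap open −5, gap extend −2) against the reference 16S FASTA;
ties go to the first-listed reference, and the BLAST-style percent identity
(identical columns / alignment columns) shades each node of the final
network so weak OTU–genome pairings stay visible.

## Worked example

```sh
pairmint make-fixtures --seed 1 --out toy_study
pairmint run-all \
    --associations toy_study/associations.tsv \
    --sequences   toy_study/queries.fasta \
    --reference   toy_study/reference.fasta \
    --models-dir  toy_study/models \
    --diet        toy_study/diets/complete.tsv \
    --out out
cat out/widget6/interactions.tsv
```

```
genome_a	genome_b	change_a	change_b	type	polarity
mutA	mutB	100	100	mutualism	positive
cmsA	cmsB	0	OBLIGATE_GAIN	commensalism	positive
parA	parB	50	-50	parasitism	negative
cmpA	cmpB	-50	-50	competition	negative
ameA	ameB	0	-50	amensalism	negative
neuA	neuB	0	0	neutralism	none
```

The toy study pairs twelve synthetic species into six communities, one per
interaction type. Reading the mutualism row: each partner grows 100 % faster
with the other present (cross-fed byproducts unlock a higher-yield route),
so the pair is typed mutualism with positive polarity. `cmsB` shows
`OBLIGATE_GAIN`: it cannot grow at all without its partner's byproduct.
`out/widget6/summary.json` reports the polarity split (33.3 % positive,
50.0 % negative, 16.7 % none), and `out/widget7/` holds the network as JSON,
GraphML and a self-contained HTML/SVG rendering (green/red/grey edges;
node shade = OTU–genome identity).

Each stage can also run on its own (`filter-otus`, `match-genomes`,
`get-models`, `merge-pairs`, `simulate-growth`, `classify`, `draw-network`);
stages communicate only through files in `--out`, so any intermediate can be
swapped for your own. From Python, the same surface is importable
(`pairmint.build_community`, `community_growth`, `classify`, …) — see
`examples/` for short narrative scripts.

## Diets

A diet is a TSV (`metabolite<TAB>flux`) of maximum uptake fluxes keyed by
lumen metabolite id. The packaged toy `complete` diet supplies every fixture
substrate at 100 mmol/gDW/hr; `--diet-scale 0.1` or `0.01` reproduce the
"/10" and "/100" reduced-availability variants. Lower availability can only
lower the joint community growth (each scaled LP is a restriction), which is
how nutrient limitation shifts communities toward competition.

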