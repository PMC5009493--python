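# Methods

This note records the model, the numerical choices and the limits of what
the synthetic tests demonstrate. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Constraint-based model and FBA

A `MetabolicModel` is a stoichiometric matrix S with per-reaction flux
bounds and a biomass pseudo-reaction whose flux (1/hr) is the growth
estimate. Flux balance analysis maximizes a linear objective over
{v : S·v = 0, lb ≤ v ≤ ub} with the HiGHS LP solver (scipy.optimize.linprog,
solver defaults; feasibility/optimality tolerances are HiGHS's ~1e-9).
Reported comparisons use an absolute tolerance of 1e-6. Infeasible and
unbounded solves carry status flags, a zero objective and no fluxes; growth
is treated as zero downstream.

SBML I/O targets one dialect — Level 3 Version 1 with FBC v2 — so that
round-trips are exact: bounds are FBC parameter references, the objective is
an FBC objective. Files with legacy note-encoded bounds are rejected with a
pointed message rather than half-read. Biomass detection: the unique
reaction with positive objective coefficient; several such reactions is an
error for single-species models; none falls back to the unique reaction
whose id or name matches `/biomass/i` (the naming convention of automated
ModelSEED-style reconstructions). Community SBML is read with
`require_biomass=False` since both member biomasses legitimately carry
positive coefficients and the solve-time objective is chosen explicitly.

## Community construction

Two models are joined through a fictitious lumen compartment `u`. Choices
that the underlying approach leaves open, fixed here:

* **Join key.** Species extracellular metabolites map to lumen metabolites
  by rewriting the compartment suffix of the *un-namespaced* id
  (`cpd00027_e` → `cpd00027_u`). This presumes both models share a compound
  namespace, as models from one reconstruction pipeline do. Ids that do not
  encode their compartment get `_u` appended.
* **Exchanges become transports.** Each species exchange on an extracellular
  metabolite is *replaced* by a reversible transport `M_e ↔ M_u` with bounds
  ±1000 (the conventional unbounded sentinel), so the lumen is the only
  boundary and a diet cannot be bypassed. Boundary reactions on
  non-extracellular metabolites (e.g. intracellular biomass sinks) stay
  species-private.
* **Namespacing** prefixes every id and compartment with `tag__`;
  re-namespacing an already tagged model is refused, which prevents
  accidentally merging a community as if it were a species.

Silencing a species zeroes both bounds of all its reactions, lumen
transports included; community exchanges are untouched.

## Diets and the four growth rates

A diet maps lumen metabolite ids to maximum uptake fluxes (mmol/gDW/hr,
≥ 0). Application sets each community exchange to `[-d(M), 1000]`, and
`[0, 1000]` for metabolites not in the diet — uptake closed, secretion
always open. Scaling a diet by 0.1/0.01 produces the reduced-availability
variants; since scaling only tightens bounds, the joint optimum is
non-increasing in the scale (verified as an invariant).

The joint objective is the **unweighted sum** of the two biomass fluxes.
Pure competition makes that optimum degenerate: only the sum is determined,
and which vertex an LP solver returns is implementation-dependent. The
default `fair` mode therefore adds one epigraph LP — hold the sum at its
optimum (slack 1e-9) and maximize min(v_A, v_B) — giving deterministic,
solver-independent growth splits; `vertex` mode preserves raw-solver
behaviour for fidelity to older tooling. Growth below 1e-9 is clamped to
exactly 0; "the species grows" means > 1e-6 wherever that distinction
matters (obligate-gain detection).

Species-level internal bounds are never touched by the diet; only the lumen
boundary is. "Alone" growth is computed inside the community with the
partner silenced, which is provably equivalent (and tested to 1e-6) to
solving the single-species model with its own exchanges bounded by the same
diet.

## Interaction typing

Percent change per species, sign with a **strict** 10 % threshold (changes
of exactly ±10 % count as no interaction), sign-pair → type table, and
polarity per type. Zero isolated growth with positive community growth is an
obligate association; its percent change is undefined, so it is carried as
the `OBLIGATE_GAIN` sentinel (`math.inf`), serialized literally in the TSV,
and always counts as `+`. Summary percentages are rounded half-up to one
decimal, matching how such results are conventionally printed.

## 16S matching

Local alignment with match +2, mismatch −3, gap open −5, gap extend −2
(BLASTN-like; a length-k gap scores −5 − 2(k−1)), via Biopython's
PairwiseAligner. Sequences are uppercased and U→T normalized; IUPAC
ambiguity characters never score as matches. Percent identity is identical
columns over total alignment columns of the best local alignment (BLAST
`pident` convention). Ties between references go to the first listed.
Queries under 16 nt are skipped with a warning. No identity threshold is
imposed: poor matches are carried through and exposed by node shading
(5-step grey ramp over 80–100 %, lightest shade plus dashed border below
80 %) rather than silently dropped. A hook for an external `blastn` binary
exists for large reference sets but is never required.

## Synthetic fixtures

The generator emulates all five input kinds at toy scale. The six model
pairs are minimal LPs whose four growth rates have closed forms under a
substrate cap of 10 mmol/gDW/hr (quadruples as (a alone, a together,
b alone, b together)): neutralism (10,10,10,10); competition (10,5,10,5) —
the fair split halves the contested substrate; commensalism (10,10,0,10) —
an obligate gain; mutualism (10,20,10,20) — byproduct exchange unlocks a
yield-3 route, and the fair split resolves the degenerate optimal face at
(20,20); parasitism (10,15,10,5) — uniquely optimal joint solution, the
host loses; amensalism (10,10,20,10) — only the generalist is penalized.
The parasitism and competition motifs deliberately exercise the degeneracy
resolution; expected values are stated under `fair` mode.

The toy "complete" diet supplies every fixture *substrate* at
100 mmol/gDW/hr. Cross-fed byproducts are deliberately not dietary: a diet
that handed out the byproducts would dissolve the engineered dependencies
(the mutualists would no longer need each other). Classification is
invariant to the overall diet scale for these linear motifs, so the types
hold under both the pair diets (cap 10) and the complete diet (cap 100).

16S fixtures are 150-nt uniform-random sequences; queries carry 0–5 planted
interior substitutions (≥10 nt from either end so the local alignment spans
the full sequence and identity is exactly (150−k)/150); the first query is
always an exact copy as a positive control. The toy study pairs twelve
species into six OTU associations, one per interaction kind.

**What passing these tests does and does not show.** The fixtures validate
the machinery — merging, solving, degeneracy handling, typing, plumbing —
against independent oracles (brute-force vertex enumeration for the LPs, a
quadratic-time Gotoh DP for alignment, COBRApy for one cross-read). They do
not emulate genome-scale models: real reconstructions bring thousands of
reactions, gap-filling artifacts, alternate pathways and blocked reactions,
and real 16S data brings chimeras, length variation and taxa without
sequenced relatives. Predictions on real data inherit the quality of the
user's models, and the pairwise design ignores effects of third species on
a pair's interaction.

## Problem sizes and determinism

Tests and the acceptance script run on the six-pair toy study (communities
of 7–16 reactions), 100 random alignment pairs of 60–200 nt, and
worked-example summaries over 754 records — sizes chosen so the whole suite
solves in seconds while every oracle stays brute-forceable. All randomness
flows through explicit seeds (study generation, layout seed 42 with 100
Fruchterman–Reingold iterations for the HTML rendering), and every output
table is byte-deterministic; determinism is itself asserted end to end.

## Known limitations

* Two-species communities only; no abundance weighting, no dynamic FBA,
  no flux variability or thermodynamic constraints.
* Model reconstruction and gap-filling are out of scope: models are loaded
  from a local directory keyed by genome id (`LocalModelProvider`); its
  `get()` interface is the extension point for a remote backend.
* The joint objective is the unweighted biomass sum; no growth-rate
  coupling between partners is imposed.
* Only SBML L3 + FBC v2 is accepted; legacy bound encodings are rejected
  rather than guessed at.
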