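"""Desk-scale synthetic inputs with analytically known answers.

Six minimal two-species model motifs, one per ecological interaction type,
built so the four growth rates of each pair have closed-form LP solutions:

* **neutralism** — disjoint substrates S1, S2 (uptake cap 10, biomass yield 1
  per substrate unit): each species grows at 10 alone and together.
* **competition** — one shared substrate S (cap 10, yield 1 each): 10 alone;
  together only the sum (10) is determined, and the fair max-min resolution
  splits it 5/5.
* **commensalism** — A converts S to biomass plus a byproduct P; B grows only
  on P: A is unaffected (10/10), B grows 0 alone and 10 together (an obligate
  gain).
* **mutualism** — each species has a plain route (yield 1, secreting a
  byproduct) and an enhanced route (yield 3) consuming the partner's
  byproduct: 10 alone, 20 together each under the fair split.
* **parasitism** — A has a plain route plus an enhanced route consuming B's
  byproduct P; B secretes P at yield 1 from the shared substrate: the joint
  optimum is unique at (15, 5) against 10 alone for both.
* **amensalism** — A lives only on the shared S; B can also use its private
  S2: alone 10 and 20; together the fair split gives (10, 10), so only B is
  penalized.

Substrate and byproduct ids are prefixed per motif (e.g. ``mut_S1_e``) so all
six pairs can coexist in one study with one substrate-only "complete" diet.
The generators are deterministic for a given seed; fixtures are regenerated
at run time rather than shipped as data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diet_fba import Diet, write_diet
from .model_core import MetabolicModel, Metabolite, Reaction, write_sbml
from .otu_prep import SequenceRecord, write_fasta

__all__ = [
    "FIXTURE_KINDS",
    "FixtureSpec",
    "make_toy_pair",
    "make_toy_reference",
    "make_toy_study",
]

FIXTURE_KINDS = (
    "mutualism",
    "commensalism",
    "parasitism",
    "competition",
    "amensalism",
    "neutralism",
)

_ABBREV = {
    "mutualism": "mut",
    "commensalism": "cms",
    "parasitism": "par",
    "competition": "cmp",
    "amensalism": "ame",
    "neutralism": "neu",
}

#: Per-pair dietary substrate cap (mmol/gDW/hr) under which the expected
#: growth quadruples below hold exactly.
SUBSTRATE_CAP = 10.0

#: Availability of every substrate in the toy "complete" diet, mirroring a
#: nutrient-rich condition; classifications are invariant to this scale.
COMPLETE_DIET_FLUX = 100.0


@dataclass
class FixtureSpec:
    """What a generated fixture pair is engineered to show."""

    kind: str
    seed: int
    expected_type: str
    #: (g_a_alone, g_a_together, g_b_alone, g_b_together) under the pair diet,
    #: fair degeneracy resolution.
    expected_growths: tuple[float, float, float, float]
    #: Lumen ids of dietary substrates (what the complete diet must supply).
    substrates: tuple[str, ...] = ()


def _species(
    model_id: str,
    prefix: str,
    tag: str,
    routes: list[tuple[dict[str, float], float]],
) -> MetabolicModel:
    """Build one toy species from (extracellular stoichiometry, yield) routes.

    Each route consumes/produces the given prefixed extracellular metabolites
    and produces ``yield`` units of the species' private biomass precursor.
    Exchanges are added for every extracellular metabolite touched.
    """
    model = MetabolicModel(id=model_id)
    x_id = f"{prefix}X{tag}_c"
    model.add_metabolite(Metabolite(x_id, name=f"{tag} biomass precursor", compartment="c"))
    ext: dict[str, Metabolite] = {}
    for stoich, _ in routes:
        for met_id in stoich:
            if met_id not in ext:
                ext[met_id] = Metabolite(met_id, compartment="e")
    for met in ext.values():
        model.add_metabolite(met)
    for met_id in ext:
        base = met_id[:-2] if met_id.endswith("_e") else met_id
        model.add_reaction(
            Reaction(f"EX_{base}", {met_id: -1.0}, -1000.0, 1000.0)
        )
    for i, (stoich, x_yield) in enumerate(routes, start=1):
        full = dict(stoich)
        full[x_id] = x_yield
        model.add_reaction(Reaction(f"R{tag}{i}", full, 0.0, 1000.0))
    model.add_reaction(
        Reaction(
            f"BIOMASS_{tag}", {x_id: -1.0}, 0.0, 1000.0, objective_coefficient=1.0
        )
    )
    model.biomass_reaction_id = f"BIOMASS_{tag}"
    model.validate()
    return model


def _motif(kind: str, prefix: str, id_a: str, id_b: str):
    p = prefix
    if kind == "neutralism":
        a = _species(id_a, p, "A", [({f"{p}S1_e": -1.0}, 1.0)])
        b = _species(id_b, p, "B", [({f"{p}S2_e": -1.0}, 1.0)])
        subs = (f"{p}S1_u", f"{p}S2_u")
        growths = (10.0, 10.0, 10.0, 10.0)
    elif kind == "competition":
        a = _species(id_a, p, "A", [({f"{p}S_e": -1.0}, 1.0)])
        b = _species(id_b, p, "B", [({f"{p}S_e": -1.0}, 1.0)])
        subs = (f"{p}S_u",)
        growths = (10.0, 5.0, 10.0, 5.0)
    elif kind == "commensalism":
        a = _species(id_a, p, "A", [({f"{p}S_e": -1.0, f"{p}P_e": 1.0}, 1.0)])
        b = _species(id_b, p, "B", [({f"{p}P_e": -1.0}, 1.0)])
        subs = (f"{p}S_u",)
        growths = (10.0, 10.0, 0.0, 10.0)
    elif kind == "mutualism":
        a = _species(
            id_a,
            p,
            "A",
            [
                ({f"{p}S1_e": -1.0, f"{p}P_e": 1.0}, 1.0),
                ({f"{p}S1_e": -1.0, f"{p}Q_e": -1.0}, 3.0),
            ],
        )
        b = _species(
            id_b,
            p,
            "B",
            [
                ({f"{p}S2_e": -1.0, f"{p}Q_e": 1.0}, 1.0),
                ({f"{p}S2_e": -1.0, f"{p}P_e": -1.0}, 3.0),
            ],
        )
        subs = (f"{p}S1_u", f"{p}S2_u")
        growths = (10.0, 20.0, 10.0, 20.0)
    elif kind == "parasitism":
        a = _species(
            id_a,
            p,
            "A",
            [
                ({f"{p}S_e": -1.0}, 1.0),
                ({f"{p}S_e": -1.0, f"{p}P_e": -1.0}, 3.0),
            ],
        )
        b = _species(id_b, p, "B", [({f"{p}S_e": -1.0, f"{p}P_e": 1.0}, 1.0)])
        subs = (f"{p}S_u",)
        growths = (10.0, 15.0, 10.0, 5.0)
    elif kind == "amensalism":
        a = _species(id_a, p, "A", [({f"{p}S_e": -1.0}, 1.0)])
        b = _species(
            id_b,
            p,
            "B",
            [({f"{p}S_e": -1.0}, 1.0), ({f"{p}S2_e": -1.0}, 1.0)],
        )
        subs = (f"{p}S_u", f"{p}S2_u")
        growths = (10.0, 10.0, 20.0, 10.0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return a, b, subs, growths


def make_toy_pair(
    kind: str, seed: int = 0
) -> tuple[MetabolicModel, MetabolicModel, Diet, FixtureSpec]:
    """Build the two species models, pair diet and expectations for *kind*."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    abbrev = _ABBREV[kind]
    a, b, subs, growths = _motif(kind, f"{abbrev}_", f"{abbrev}A", f"{abbrev}B")
    diet = Diet(name=f"{kind}_pair", fluxes={s: SUBSTRATE_CAP for s in subs})
    spec = FixtureSpec(
        kind=kind,
        seed=seed,
        expected_type=kind,
        expected_growths=growths,
        substrates=subs,
    )
    return a, b, diet, spec


_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Plant *n_subs* substitutions away from the ends (so local alignment
    spans the full sequence and identity is exactly (L−n)/L)."""
    chars = list(seq)
    interior = np.arange(10, len(chars) - 10)
    for pos in rng.choice(interior, size=n_subs, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def make_toy_reference(
    n_genomes: int,
    seed: int = 0,
    outdir: str | Path | None = None,
    length: int = 150,
    max_edits: int = 5,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[tuple[str, str, float]]]:
    """Random 16S-like reference genomes plus queries with planted edits.

    Returns (reference records, query records, expected matches) where each
    expected match is ``(query_id, genome_id, percent_identity)`` computed
    from the planted substitution count.  The first query is always an exact
    copy of its genome (a positive control for the 100 %-identity self-match
    property).  With *outdir* set, also writes
    ``reference.fasta`` and ``queries.fasta`` (byte-identical across runs with
    the same seed).
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    rng = np.random.default_rng(seed)
    reference = [
        SequenceRecord(f"G{i + 1:04d}", _random_sequence(rng, length))
        for i in range(n_genomes)
    ]
    queries: list[SequenceRecord] = []
    expected: list[tuple[str, str, float]] = []
    for i, ref in enumerate(reference):
        n_subs = 0 if i == 0 else int(rng.integers(0, max_edits + 1))
        queries.append(SequenceRecord(f"otu{i + 1:03d}", _mutate(rng, ref.sequence, n_subs)))
        expected.append(
            (queries[-1].id, ref.id, round(100.0 * (length - n_subs) / length, 6))
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, outdir / "reference.fasta")
        write_fasta(queries, outdir / "queries.fasta")
    return reference, queries, expected


def make_toy_study(seed: int = 0, outdir: str | Path = "toy_study") -> Path:
    """Write a complete six-pair study directory, runnable end-to-end.

    Contents: ``associations.tsv`` (one OTU pair per interaction kind),
    ``queries.fasta`` / ``reference.fasta`` (OTU and genome 16S sequences,
    queries carrying 1–3 planted substitutions), ``models/<genome>.xml`` (the
    twelve fixture species models), ``diets/complete.tsv`` (every fixture
    substrate at 100 mmol/gDW/hr) and a ``study.json`` manifest recording the
    engineered expectations.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "diets").mkdir(parents=True, exist_ok=True)

    assoc_rows: list[str] = []
    reference: list[SequenceRecord] = []
    queries: list[SequenceRecord] = []
    substrates: dict[str, float] = {}
    manifest: dict[str, dict] = {}
    otu_counter = 0

    for i, kind in enumerate(FIXTURE_KINDS):
        model_a, model_b, _pair_diet, spec = make_toy_pair(kind, seed=seed)
        for model in (model_a, model_b):
            write_sbml(model, outdir / "models" / f"{model.id}.xml")
            otu_counter += 1
            otu_id = f"otu{otu_counter:03d}"
            seq = _random_sequence(rng, 150)
            reference.append(SequenceRecord(model.id, seq))
            queries.append(
                SequenceRecord(otu_id, _mutate(rng, seq, int(rng.integers(1, 4))))
            )
        otu_a, otu_b = queries[-2].id, queries[-1].id
        weight = round(0.4 + 0.09 * i, 2)
        assoc_rows.append(f"{otu_a}\t{otu_b}\t{weight}")
        for s in spec.substrates:
            substrates[s] = COMPLETE_DIET_FLUX
        manifest[kind] = {
            "genome_a": model_a.id,
            "genome_b": model_b.id,
            "otu_a": otu_a,
            "otu_b": otu_b,
            "expected_type": spec.expected_type,
            "expected_growths": list(spec.expected_growths),
            "substrates": list(spec.substrates),
        }

    (outdir / "associations.tsv").write_text(
        "otu_a\totu_b\tweight\n" + "\n".join(assoc_rows) + "\n"
    )
    write_fasta(reference, outdir / "reference.fasta")
    write_fasta(queries, outdir / "queries.fasta")
    write_diet(Diet(name="complete", fluxes=substrates), outdir / "diets" / "complete.tsv")
    (outdir / "study.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
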