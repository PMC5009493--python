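"""Merge two single-species models into a two-species community model.

The merge follows the multi-species stoichiometric approach of introducing a
fictitious shared extracellular compartment (the "lumen", compartment token
``u``): every id of each input model is namespaced with a species tag, each
species exchange reaction on an extracellular metabolite is *replaced* by a
reversible transport between the species' own extracellular metabolite and the
corresponding lumen metabolite, and one community exchange reaction per lumen
metabolite becomes the model's only boundary with the environment.  The lumen
is therefore the single surface on which a diet can act, and metabolites cross
between species only through it.

The join key between the two species' extracellular metabolites is the
un-namespaced metabolite id with its compartment suffix rewritten (e.g.
``cpd00027_e`` in both models becomes one shared ``cpd00027_u``): models from
a common reconstruction pipeline (such as ModelSEED) share a compound
namespace, which is what makes the lumen meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CommunityBuildError, UnmatchedOTUError
from .model_core import MetabolicModel, Metabolite, Reaction, exchange_reactions
from .otu_prep import AssociationTable, GenomeMatch

__all__ = [
    "SpeciesTag",
    "CommunityModel",
    "PairList",
    "pair_list",
    "namespace_model",
    "build_community",
    "silence_species",
    "TRANSPORT_BOUND",
]

logger = logging.getLogger(__name__)

#: Conventional "unbounded" sentinel for lumen transports and community exchanges.
TRANSPORT_BOUND = 1000.0

EXTRACELLULAR_COMPARTMENT = "e"
LUMEN_COMPARTMENT = "u"


def _check_tag(tag: str) -> str:
    if not tag or any(c.isspace() for c in tag):
        raise ValueError(f"species tag must be a non-empty token, got {tag!r}")
    return tag


@dataclass
class CommunityModel:
    """Two namespaced species models joined through a shared lumen."""

    base: MetabolicModel
    tags: tuple[str, str]
    biomass_ids: dict[str, str]
    id_map: dict[str, dict[str, str]] = field(default_factory=dict)
    lumen_compartment: str = LUMEN_COMPARTMENT
    pair: tuple[str, str] | None = None  # originating genome ids

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            base=self.base.copy(),
            tags=self.tags,
            biomass_ids=dict(self.biomass_ids),
            id_map={t: dict(m) for t, m in self.id_map.items()},
            lumen_compartment=self.lumen_compartment,
            pair=self.pair,
        )

    def community_exchanges(self) -> list[str]:
        """Ids of the lumen boundary reactions (``EX_M_u: M_u → ∅``)."""
        out = []
        for rid in exchange_reactions(self.base):
            (met_id,) = self.base.reactions[rid].stoichiometry
            if self.base.metabolites[met_id].compartment == self.lumen_compartment:
                out.append(rid)
        return out


class PairList:
    """Unordered-unique genome pairs, with the originating OTU pair kept."""

    def __init__(
        self, pairs: Iterable[tuple[str, str] | tuple[str, str, tuple[str, str]]]
    ):
        self.pairs: list[tuple[str, str]] = []
        self.otu_pairs: list[tuple[str, str] | None] = []
        seen: set[frozenset[str]] = set()
        for entry in pairs:
            a, b = entry[0], entry[1]
            otus = entry[2] if len(entry) > 2 else None
            if a == b:
                raise ValueError(f"a genome cannot be paired with itself: {a!r}")
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            self.pairs.append((a, b))
            self.otu_pairs.append(otus)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def pair_list(
    assoc: AssociationTable, matches: Sequence[GenomeMatch]
) -> PairList:
    """Map each OTU association to a genome pair.

    Rows whose two OTUs resolve to the same genome are dropped with a warning
    (a species does not form a pair with itself); duplicate genome pairs are
    collapsed.  An OTU without a genome match is an error.
    """
    genome_of = {m.otu_id: m.genome_id for m in matches}
    entries: list[tuple[str, str, tuple[str, str]]] = []
    for otu_a, otu_b, _w in assoc:
        for otu in (otu_a, otu_b):
            if otu not in genome_of:
                raise UnmatchedOTUError(
                    f"OTU {otu!r} in the association table has no genome match"
                )
        ga, gb = genome_of[otu_a], genome_of[otu_b]
        if ga == gb:
            logger.warning(
                "association (%s, %s) maps both OTUs to genome %s; dropped",
                otu_a,
                otu_b,
                ga,
            )
            continue
        entries.append((ga, gb, (otu_a, otu_b)))
    return PairList(entries)


def namespace_model(
    model: MetabolicModel, tag: str
) -> tuple[MetabolicModel, dict[str, str]]:
    """Prefix every metabolite id, reaction id and compartment with ``tag__``.

    Returns the renamed copy and the bijective original-id → namespaced-id map
    (covering both metabolites and reactions).  Namespacing an already
    namespaced model is refused.
    """
    _check_tag(tag)
    prefix = f"{tag}__"
    for mid, met in model.metabolites.items():
        if "__" in met.compartment:
            raise ValueError(
                f"model {model.id!r} appears to be namespaced already "
                f"(compartment {met.compartment!r})"
            )
        if mid.startswith(prefix):
            raise ValueError(f"metabolite {mid!r} already carries tag {tag!r}")
    id_map: dict[str, str] = {}
    out = MetabolicModel(id=f"{prefix}{model.id}")
    for met in model.metabolites.values():
        id_map[met.id] = prefix + met.id
        out.add_metabolite(
            Metabolite(
                id=prefix + met.id,
                name=met.name,
                compartment=prefix + met.compartment,
            )
        )
    for rxn in model.reactions.values():
        id_map[rxn.id] = prefix + rxn.id
        out.add_reaction(
            Reaction(
                id=prefix + rxn.id,
                stoichiometry={prefix + m: c for m, c in rxn.stoichiometry.items()},
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                objective_coefficient=rxn.objective_coefficient,
            )
        )
    if model.biomass_reaction_id is not None:
        out.biomass_reaction_id = prefix + model.biomass_reaction_id
    return out, id_map


def _lumen_id(met: Metabolite, lumen: str) -> str:
    """Lumen metabolite id for an extracellular metabolite.

    ``cpd00027_e`` → ``cpd00027_u``; ids that do not encode their compartment
    get the lumen suffix appended.
    """
    suffix = f"_{met.compartment}"
    base = met.id[: -len(suffix)] if met.id.endswith(suffix) else met.id
    return f"{base}_{lumen}"


def build_community(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    tag_a: str = "A",
    tag_b: str = "B",
    lumen: str = LUMEN_COMPARTMENT,
) -> CommunityModel:
    """Merge two valid single-species models into a community model.

    Each species exchange reaction on an extracellular metabolite M becomes a
    reversible transport ``tag__M_e ↔ M_u`` with bounds ±1000; one community
    exchange ``EX_M_u: M_u → ∅`` (bounds ±1000 until a diet is applied) is
    added per distinct lumen metabolite.  Exchange reactions on non-
    extracellular metabolites (e.g. intracellular biomass sinks) are kept as
    species-private boundaries.  The community objective is left unset; it is
    chosen at solve time.
    """
    _check_tag(tag_a)
    _check_tag(tag_b)
    if tag_a == tag_b:
        raise ValueError(f"species tags must differ, both are {tag_a!r}")
    for m in (model_a, model_b):
        m.validate()

    base = MetabolicModel(id=f"community__{tag_a}__{tag_b}")
    biomass_ids: dict[str, str] = {}
    id_maps: dict[str, dict[str, str]] = {}
    lumen_mets: dict[str, Metabolite] = {}
    genome_ids = (model_a.id, model_b.id)

    for model, tag in ((model_a, tag_a), (model_b, tag_b)):
        ext_exchanges = [
            rid
            for rid in exchange_reactions(model)
            if model.metabolites[
                next(iter(model.reactions[rid].stoichiometry))
            ].compartment
            == EXTRACELLULAR_COMPARTMENT
        ]
        if not ext_exchanges:
            raise CommunityBuildError(
                f"model {model.id!r} has no extracellular exchange reactions; "
                "nothing can be shared through the lumen"
            )
        ns_model, id_map = namespace_model(model, tag)
        id_maps[tag] = id_map
        biomass_ids[tag] = id_map[model.biomass_reaction_id]
        ns_exchange_ids = {id_map[rid] for rid in ext_exchanges}

        for met in ns_model.metabolites.values():
            base.add_metabolite(met)
        for rxn in ns_model.reactions.values():
            if rxn.id in ns_exchange_ids:
                (ns_met_id,) = rxn.stoichiometry
                orig_met_id = ns_met_id[len(tag) + 2 :]
                orig_met = model.metabolites[orig_met_id]
                lid = _lumen_id(orig_met, lumen)
                if lid not in lumen_mets:
                    lumen_mets[lid] = Metabolite(
                        id=lid, name=orig_met.name, compartment=lumen
                    )
                # Exchange replaced in place by a lumen transport.
                rxn = Reaction(
                    id=rxn.id,
                    stoichiometry={ns_met_id: -1.0, lid: 1.0},
                    lower_bound=-TRANSPORT_BOUND,
                    upper_bound=TRANSPORT_BOUND,
                    objective_coefficient=0.0,
                )
            base.reactions[rxn.id] = rxn  # deferred validation: lumen mets added below

    for lid, met in lumen_mets.items():
        if lid in base.metabolites:
            raise CommunityBuildError(
                f"lumen metabolite id {lid!r} collides with a species metabolite"
            )
        base.add_metabolite(met)
    for lid in lumen_mets:
        ex_id = f"EX_{lid}"
        if ex_id in base.reactions:
            raise CommunityBuildError(f"community exchange id {ex_id!r} collides")
        base.reactions[ex_id] = Reaction(
            id=ex_id,
            stoichiometry={lid: -1.0},
            lower_bound=-TRANSPORT_BOUND,
            upper_bound=TRANSPORT_BOUND,
        )
    base.validate()
    return CommunityModel(
        base=base,
        tags=(tag_a, tag_b),
        biomass_ids=biomass_ids,
        id_map=id_maps,
        lumen_compartment=lumen,
        pair=genome_ids,
    )


def silence_species(community: CommunityModel, tag: str) -> CommunityModel:
    """Zero both bounds of every reaction of one species (lumen transports
    included); community exchanges are untouched.

    Used to estimate a species' growth "in isolation" inside the community
    context: the partner's entire metabolism, including its access to the
    lumen, is switched off.
    """
    if tag not in community.tags:
        raise KeyError(f"unknown species tag {tag!r}; community has {community.tags}")
    out = community.copy()
    prefix = f"{tag}__"
    for rxn in out.base.reactions.values():
        if rxn.id.startswith(prefix):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
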