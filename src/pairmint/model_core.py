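"""Domain types and I/O for single-species constraint-based metabolic models.

A :class:`MetabolicModel` is a lightweight, explicit container for the
stoichiometry, flux bounds and biomass objective of a genome-scale metabolic
reconstruction.  Models are read from and written to SBML Level 3 Version 1
with the Flux Balance Constraints (FBC) version 2 package — the dialect in
which reaction bounds are parameter references and the objective is an FBC
objective list.  Legacy note-encoded bounds are rejected with a clear message.

Flux balance analysis (:func:`fba`) maximizes a linear objective over the flux
cone ``S·v = 0`` subject to the per-reaction bounds, using the HiGHS linear
programming solver.  Growth rates are in 1/hr and exchange fluxes in
mmol/gDW/hr throughout.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import NoBiomassError, SBMLParseError

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "SolveStatus",
    "read_sbml",
    "write_sbml",
    "exchange_reactions",
    "fba",
]

#: Absolute tolerance on mass balance and bound feasibility of reported fluxes.
FLUX_TOLERANCE = 1e-6

_BIOMASS_RE = re.compile(r"biomass", re.IGNORECASE)


@dataclass
class Metabolite:
    """A chemical species localized to one compartment (e.g. ``c``, ``e``, ``u``)."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to coefficient; negative coefficients
    are consumed, positive produced.  ``objective_coefficient`` marks the
    reaction's weight in the model's default (biomass) objective.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    objective_coefficient: float = 0.0

    def validate(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ValueError(
                    f"reaction {self.id!r}: coefficient for {met!r} must be finite and nonzero"
                )
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, bounded reactions, biomass objective.

    ``biomass_reaction_id`` may be ``None`` for intermediate models whose
    objective is assigned at solve time (e.g. two-species communities).
    """

    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        rxn.validate()
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate()
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
        if self.biomass_reaction_id is not None:
            bio = self.reactions.get(self.biomass_reaction_id)
            if bio is None:
                raise ValueError(
                    f"biomass_reaction_id {self.biomass_reaction_id!r} not in model"
                )
            if bio.objective_coefficient <= 0:
                raise ValueError(
                    f"biomass reaction {bio.id!r} must have objective_coefficient > 0"
                )

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


class SolveStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    """Outcome of one linear-programming solve.

    Non-optimal statuses carry an objective of 0 and no fluxes; downstream the
    corresponding growth rate is treated as zero.
    """

    status: SolveStatus
    objective_value: float = 0.0
    fluxes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 Version 1 + FBC v2)
# ---------------------------------------------------------------------------


def _import_libsbml():
    import libsbml

    return libsbml


def read_sbml(path: str | Path, require_biomass: bool = True) -> MetabolicModel:
    """Read a metabolic model from an SBML L3 + FBC file.

    Reaction bounds and objective coefficients are taken from the FBC
    annotations.  The biomass reaction is the unique reaction with a positive
    objective coefficient; if the document declares no objective, the unique
    reaction whose id or name matches ``/biomass/i`` is used instead (with an
    objective coefficient of 1), matching ModelSEED naming conventions.

    With ``require_biomass=False`` the biomass-detection step is skipped
    entirely and ``biomass_reaction_id`` is left ``None`` — appropriate for
    community models, whose objective (one or several biomass reactions) is
    chosen at solve time.
    """
    libsbml = _import_libsbml()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML file not found: {path}")
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path}: invalid SBML at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: document contains no <model> element")

    model = MetabolicModel(id=sbml_model.getId() or path.stem)

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() if sp.isSetName() else sp.getId(),
                compartment=sp.getCompartment(),
            )
        )

    def _bound_value(param_id: str, rxn_id: str, which: str) -> float:
        param = sbml_model.getParameter(param_id)
        if param is None:
            raise SBMLParseError(
                f"{path}: reaction {rxn_id!r} {which} bound references missing parameter {param_id!r}"
            )
        return param.getValue()

    names: dict[str, str] = {}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        names[rid] = rxn.getName() if rxn.isSetName() else ""
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise SBMLParseError(
                f"{path}: reaction {rid!r} lacks FBC flux bounds; "
                "legacy note-encoded bounds are not supported (re-export with FBC v2)"
            )
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=_bound_value(fbc.getLowerFluxBound(), rid, "lower"),
                upper_bound=_bound_value(fbc.getUpperFluxBound(), rid, "upper"),
            )
        )

    mplug = sbml_model.getPlugin("fbc")
    objective = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        objective = mplug.getActiveObjective() or mplug.getObjective(0)
    positive: list[str] = []
    if objective is not None:
        for j in range(objective.getNumFluxObjectives()):
            fo = objective.getFluxObjective(j)
            rid = fo.getReaction()
            if rid not in model.reactions:
                raise SBMLParseError(
                    f"{path}: objective references unknown reaction {rid!r}"
                )
            model.reactions[rid].objective_coefficient = fo.getCoefficient()
            if fo.getCoefficient() > 0:
                positive.append(rid)

    if not require_biomass:
        model.validate()
        return model

    if len(positive) > 1:
        raise NoBiomassError(
            f"{path}: multiple reactions with positive objective coefficient: {positive}"
        )
    if positive:
        model.biomass_reaction_id = positive[0]
    else:
        candidates = [
            rid
            for rid in model.reactions
            if _BIOMASS_RE.search(rid) or _BIOMASS_RE.search(names.get(rid, ""))
        ]
        if len(candidates) == 1:
            model.biomass_reaction_id = candidates[0]
            model.reactions[candidates[0]].objective_coefficient = 1.0
        elif len(candidates) > 1:
            raise NoBiomassError(
                f"{path}: no FBC objective and several /biomass/ candidates: {candidates}"
            )
        else:
            raise NoBiomassError(f"{path}: no biomass reaction")

    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    """Write *model* as SBML L3V1 + FBC v2; returns the path written.

    Round-trips with :func:`read_sbml` up to element ordering.
    """
    libsbml = _import_libsbml()
    model.validate()
    path = Path(path)

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted({m.compartment for m in model.metabolites.values()}):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sm.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    objective_terms: list[tuple[str, float]] = []
    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_param(rxn.upper_bound))
        if rxn.objective_coefficient != 0:
            objective_terms.append((rxn.id, rxn.objective_coefficient))

    if objective_terms:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, coef in objective_terms:
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(coef)
        mplug.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML to {path}")
    return path


def _sanitize_sid(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "M_" + out
    return out


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def exchange_reactions(model: MetabolicModel) -> list[str]:
    """Ids of boundary reactions, i.e. reactions touching a single metabolite.

    These model uptake from / secretion to the environment (``M ↔ ∅``); under
    the export convention, negative flux is uptake.
    """
    return [rid for rid, rxn in model.reactions.items() if len(rxn.stoichiometry) == 1]


def fba(
    model: MetabolicModel,
    objective: Mapping[str, float] | None = None,
) -> FluxSolution:
    """Flux balance analysis: maximize ``w·v`` s.t. ``S·v = 0`` and bounds.

    *objective* maps reaction ids to weights; by default the model's biomass
    reaction with weight 1.  Infeasible and unbounded problems are reported in
    the solution status with a zero objective value.
    """
    model.validate()
    if objective is None:
        if model.biomass_reaction_id is None:
            raise KeyError("model has no biomass reaction and no objective was given")
        objective = {model.biomass_reaction_id: 1.0}
    for rid in objective:
        if rid not in model.reactions:
            raise KeyError(f"objective references unknown reaction {rid!r}")

    rxn_ids = list(model.reactions)
    A_eq, bounds = _stoichiometric_lp(model, rxn_ids)
    c = np.zeros(len(rxn_ids))
    for rid, w in objective.items():
        c[rxn_ids.index(rid)] = -w  # linprog minimizes

    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution(status=SolveStatus.INFEASIBLE)
    if res.status == 3:
        return FluxSolution(status=SolveStatus.UNBOUNDED)
    if res.status != 0:
        raise RuntimeError(f"LP solver failed on model {model.id!r}: {res.message}")
    fluxes = dict(zip(rxn_ids, (float(v) for v in res.x)))
    return FluxSolution(
        status=SolveStatus.OPTIMAL,
        objective_value=float(-res.fun),
        fluxes=fluxes,
    )


def _stoichiometric_lp(
    model: MetabolicModel, rxn_ids: list[str]
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Dense stoichiometric matrix and bound list in *rxn_ids* column order."""
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    S = np.zeros((len(met_index), len(rxn_ids)))
    bounds: list[tuple[float, float]] = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met_id, coef in rxn.stoichiometry.items():
            S[met_index[met_id], j] = coef
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    return S, bounds
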