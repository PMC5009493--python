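"""Apply a diet to a community model and estimate the four growth rates.

A diet is a table of maximum uptake fluxes (mmol/gDW/hr) for lumen
metabolites.  Applying it to a community model sets the lower bound of each
community exchange ``EX_M_u`` to minus the dietary availability of M (uptake
is negative flux under the export convention); metabolites absent from the
diet cannot be taken up but can always be secreted.

For each species pair four growth rates are estimated:

* *together*: one LP maximizing the unweighted sum of the two biomass fluxes.
  Where that optimum is degenerate (e.g. pure competition for one substrate,
  where only the sum of the two growth rates is pinned down), the default
  ``fair`` mode resolves it deterministically with a second LP that holds the
  sum at its optimum and maximizes the smaller of the two biomass fluxes;
  ``vertex`` mode returns the raw solver vertex instead.
* *alone*: the same diet-constrained community with the partner's reactions
  silenced, maximizing the focal species' biomass.

Growth rates below 1e-9 are clamped to exactly 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .community_build import CommunityModel, silence_species
from .errors import FormatError
from .model_core import (
    FluxSolution,
    MetabolicModel,
    SolveStatus,
    _stoichiometric_lp,
    exchange_reactions,
    fba,
)

__all__ = [
    "Diet",
    "GrowthResult",
    "read_diet",
    "write_diet",
    "scale_diet",
    "apply_diet",
    "apply_diet_to_model",
    "community_growth",
    "write_growth_results",
    "read_growth_results",
    "GROWTH_ZERO_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Growth rates below this are stored as exactly zero.
GROWTH_ZERO_TOLERANCE = 1e-9
#: Slack when pinning the joint optimum in the fair-split LP.
_SUM_SLACK = 1e-9

SECRETION_BOUND = 1000.0


@dataclass
class Diet:
    """Maximum uptake fluxes, keyed by lumen metabolite id."""

    name: str
    fluxes: dict[str, float]

    def __post_init__(self) -> None:
        for met, v in self.fluxes.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"diet {self.name!r}: flux for {met!r} must be finite and ≥ 0, got {v}"
                )


@dataclass
class GrowthResult:
    """Four growth-rate estimates (1/hr) for one species pair."""

    pair: tuple[str, str]
    g_a_alone: float
    g_a_together: float
    g_b_alone: float
    g_b_together: float
    solve_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("g_a_alone", "g_a_together", "g_b_alone", "g_b_together"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be ≥ 0, got {v}")
            if v < GROWTH_ZERO_TOLERANCE:
                setattr(self, name, 0.0)


def read_diet(path: str | Path, name: str | None = None) -> Diet:
    """Read a diet TSV with header ``metabolite<TAB>flux``.

    Duplicate metabolites keep the last value with a warning; negative fluxes
    are a format error.
    """
    path = Path(path)
    fluxes: dict[str, float] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:2]] != ["metabolite", "flux"]:
            raise FormatError(
                f"{path}: expected header 'metabolite\\tflux', got {header!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            met = fields[0]
            try:
                flux = float(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric flux {fields[1]!r}"
                ) from None
            if flux < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative uptake flux {flux} for {met!r}"
                )
            if met in fluxes:
                logger.warning("%s:%d: duplicate metabolite %r, last value wins", path, lineno, met)
            fluxes[met] = flux
    return Diet(name=name or path.stem, fluxes=fluxes)


def write_diet(diet: Diet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("metabolite\tflux\n")
        for met, flux in diet.fluxes.items():
            handle.write(f"{met}\t{flux:.6g}\n")
    return path


def scale_diet(diet: Diet, factor: float) -> Diet:
    """Multiply every uptake flux by *factor* (> 0).

    A factor of 0.1 yields the "/10" variant of a diet, 0.01 the "/100"
    variant; the name records the division.
    """
    if not factor > 0:
        raise ValueError(f"diet scale factor must be > 0, got {factor}")
    name = diet.name
    if factor < 1:
        name = f"{name}/{1 / factor:g}"
    return Diet(name=name, fluxes={m: v * factor for m, v in diet.fluxes.items()})


def apply_diet(community: CommunityModel, diet: Diet) -> CommunityModel:
    """Bound the community exchanges by the diet (on a copy).

    ``EX_M_u`` gets lower bound −diet[M] if M is in the diet and 0 otherwise;
    the upper (secretion) bound is always 1000.  Diet metabolites without a
    matching community exchange are skipped with a log message.
    """
    out = community.copy()
    ex_of_met: dict[str, str] = {}
    for rid in out.community_exchanges():
        (met_id,) = out.base.reactions[rid].stoichiometry
        ex_of_met[met_id] = rid
        out.base.reactions[rid].lower_bound = 0.0
        out.base.reactions[rid].upper_bound = SECRETION_BOUND
    for met, flux in diet.fluxes.items():
        rid = ex_of_met.get(met)
        if rid is None:
            logger.info(
                "diet %r metabolite %r has no community exchange; skipped",
                diet.name,
                met,
            )
            continue
        out.base.reactions[rid].lower_bound = -flux
    return out


def apply_diet_to_model(model: MetabolicModel, diet: Diet) -> MetabolicModel:
    """Bound a *single-species* model's extracellular exchanges by a diet.

    The diet is keyed by lumen ids; each extracellular exchange is matched via
    the same id rewrite used when building communities (``M_e`` → ``M_u``).
    This gives the single-species growth that is equivalent to growing in a
    community with the partner silenced.
    """
    from .community_build import EXTRACELLULAR_COMPARTMENT, _lumen_id

    out = model.copy()
    for rid in exchange_reactions(out):
        rxn = out.reactions[rid]
        (met_id,) = rxn.stoichiometry
        met = out.metabolites[met_id]
        if met.compartment != EXTRACELLULAR_COMPARTMENT:
            continue
        lid = _lumen_id(met, "u")
        rxn.upper_bound = SECRETION_BOUND
        rxn.lower_bound = -diet.fluxes.get(lid, 0.0)
    return out


def community_growth(
    community: CommunityModel,
    diet: Diet,
    degeneracy: Literal["fair", "vertex"] = "fair",
) -> GrowthResult:
    """Estimate the four growth rates of a pair under a diet.

    Runs (1) the joint maximization of both biomass fluxes (with the chosen
    degeneracy resolution), and (2)–(3) one solve per species with the partner
    silenced.  Solver failures leave the affected rates at 0 with the status
    recorded.
    """
    dieted = apply_diet(community, diet)
    tag_a, tag_b = dieted.tags
    bio_a = dieted.biomass_ids[tag_a]
    bio_b = dieted.biomass_ids[tag_b]
    status: dict[str, str] = {}

    joint = fba(dieted.base, {bio_a: 1.0, bio_b: 1.0})
    status["joint"] = joint.status.value
    if joint.status is SolveStatus.OPTIMAL:
        if degeneracy == "fair":
            g_a_tog, g_b_tog = _fair_split(
                dieted.base, bio_a, bio_b, joint.objective_value
            )
        elif degeneracy == "vertex":
            g_a_tog, g_b_tog = joint.fluxes[bio_a], joint.fluxes[bio_b]
        else:
            raise ValueError(f"unknown degeneracy mode {degeneracy!r}")
    else:
        g_a_tog = g_b_tog = 0.0

    alone: dict[str, float] = {}
    for focal, partner, bio in ((tag_a, tag_b, bio_a), (tag_b, tag_a, bio_b)):
        sol = fba(silence_species(dieted, partner).base, {bio: 1.0})
        status[f"{focal}_alone"] = sol.status.value
        alone[focal] = sol.objective_value if sol.status is SolveStatus.OPTIMAL else 0.0

    return GrowthResult(
        pair=community.pair or (tag_a, tag_b),
        g_a_alone=max(alone[tag_a], 0.0),
        g_a_together=max(g_a_tog, 0.0),
        g_b_alone=max(alone[tag_b], 0.0),
        g_b_together=max(g_b_tog, 0.0),
        solve_status=status,
    )


def _fair_split(
    model: MetabolicModel, bio_a: str, bio_b: str, joint_optimum: float
) -> tuple[float, float]:
    """Max-min resolution of a degenerate joint optimum.

    One LP over (v, t): maximize t subject to S·v = 0, the flux bounds,
    v_a + v_b ≥ joint optimum − 1e-9 (its upper bound holds by optimality),
    and t ≤ v_a, t ≤ v_b.  Deterministic across solvers wherever the joint
    optimum leaves only the sum of the two growth rates determined.
    """
    rxn_ids = list(model.reactions)
    S, bounds = _stoichiometric_lp(model, rxn_ids)
    n = len(rxn_ids)
    ia, ib = rxn_ids.index(bio_a), rxn_ids.index(bio_b)

    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    A_ub = np.zeros((3, n + 1))
    A_ub[0, ia] = A_ub[0, ib] = -1.0  # -(va+vb) ≤ -(T - slack)
    A_ub[1, ia], A_ub[1, n] = -1.0, 1.0  # t - va ≤ 0
    A_ub[2, ib], A_ub[2, n] = -1.0, 1.0  # t - vb ≤ 0
    b_ub = np.array([-(joint_optimum - _SUM_SLACK), 0.0, 0.0])
    c = np.zeros(n + 1)
    c[n] = -1.0  # maximize t
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds + [(0.0, None)],
        method="highs",
    )
    if res.status != 0:
        logger.warning(
            "fair-split LP did not solve (%s); falling back to vertex resolution",
            res.message,
        )
        sol = fba(model, {bio_a: 1.0, bio_b: 1.0})
        return sol.fluxes.get(bio_a, 0.0), sol.fluxes.get(bio_b, 0.0)
    return float(res.x[ia]), float(res.x[ib])


def write_growth_results(results: Sequence[GrowthResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(
            "genome_a\tgenome_b\tg_a_alone\tg_a_together\tg_b_alone\tg_b_together\n"
        )
        for r in results:
            handle.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{r.g_a_alone:.9g}\t{r.g_a_together:.9g}"
                f"\t{r.g_b_alone:.9g}\t{r.g_b_together:.9g}\n"
            )
    return path


def read_growth_results(path: str | Path) -> list[GrowthResult]:
    path = Path(path)
    out: list[GrowthResult] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("genome_a"):
            raise FormatError(f"{path}: expected growth-table header")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            out.append(
                GrowthResult(
                    pair=(fields[0], fields[1]),
                    g_a_alone=float(fields[2]),
                    g_a_together=float(fields[3]),
                    g_b_alone=float(fields[4]),
                    g_b_together=float(fields[5]),
                )
            )
    return out
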