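"""Model container, SBML round-trips and flux balance analysis."""

import math

import numpy as np
import pytest

from _oracles import oracle_fba
from pairmint.errors import NoBiomassError, SBMLParseError
from pairmint.model_core import (
    FLUX_TOLERANCE,
    MetabolicModel,
    Metabolite,
    Reaction,
    SolveStatus,
    exchange_reactions,
    fba,
    read_sbml,
    write_sbml,
)

from conftest import linear_chain_model


class TestContainers:
    def test_reaction_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-empty"):
            Reaction("R", {}).validate()
        with pytest.raises(ValueError, match="finite and nonzero"):
            Reaction("R", {"m": 0.0}).validate()
        with pytest.raises(ValueError, match="lower_bound"):
            Reaction("R", {"m": 1.0}, lower_bound=5, upper_bound=1).validate()

    def test_unknown_metabolite_rejected(self, chain_model):
        with pytest.raises(ValueError, match="unknown metabolite"):
            chain_model.add_reaction(Reaction("R9", {"nope": 1.0}))

    def test_biomass_must_carry_positive_objective(self, chain_model):
        chain_model.reactions["BIO"].objective_coefficient = 0.0
        with pytest.raises(ValueError, match="objective_coefficient"):
            chain_model.validate()


class TestSBML:
    def test_round_trip_preserves_everything(self, chain_model, tmp_path):
        path = write_sbml(chain_model, tmp_path / "m.xml")
        back = read_sbml(path)
        assert back.biomass_reaction_id == "BIO"
        assert set(back.reactions) == set(chain_model.reactions)
        assert set(back.metabolites) == set(chain_model.metabolites)
        for rid, rxn in chain_model.reactions.items():
            assert back.reactions[rid].stoichiometry == rxn.stoichiometry
            assert back.reactions[rid].lower_bound == rxn.lower_bound
            assert back.reactions[rid].upper_bound == rxn.upper_bound
            assert (
                back.reactions[rid].objective_coefficient == rxn.objective_coefficient
            )
        for mid, met in chain_model.metabolites.items():
            assert back.metabolites[mid].compartment == met.compartment

    def test_unicode_names_survive_round_trip(self, chain_model, tmp_path):
        chain_model.metabolites["S_e"].name = "α-D-глюкоза"
        back = read_sbml(write_sbml(chain_model, tmp_path / "m.xml"))
        assert back.metabolites["S_e"].name == "α-D-глюкоза"

    def test_biomass_fallback_by_name(self, chain_model, tmp_path):
        # Strip the FBC objective: detection must fall back to /biomass/i.
        chain_model.reactions["BIO"].objective_coefficient = 0.0
        chain_model.biomass_reaction_id = None
        renamed = MetabolicModel(id="m", metabolites=chain_model.metabolites)
        for rid, rxn in chain_model.reactions.items():
            rxn.id = "bio1_biomass" if rid == "BIO" else rid
            renamed.reactions[rxn.id] = rxn
        path = write_sbml(renamed, tmp_path / "m.xml")
        back = read_sbml(path)
        assert back.biomass_reaction_id == "bio1_biomass"
        assert back.reactions["bio1_biomass"].objective_coefficient > 0

    def test_no_biomass_is_an_error(self, chain_model, tmp_path):
        chain_model.reactions["BIO"].objective_coefficient = 0.0
        chain_model.biomass_reaction_id = None
        path = write_sbml(chain_model, tmp_path / "m.xml")
        with pytest.raises(NoBiomassError, match="no biomass"):
            read_sbml(path)

    def test_empty_file_is_a_parse_error(self, tmp_path):
        empty = tmp_path / "empty.xml"
        empty.write_text("")
        with pytest.raises(SBMLParseError):
            read_sbml(empty)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sbml(tmp_path / "nope.xml")


class TestExchangeDetection:
    def test_single_metabolite_reactions_only(self, chain_model):
        assert set(exchange_reactions(chain_model)) == {"EX_S", "BIO"}

    def test_no_exchanges(self):
        m = MetabolicModel(id="closed")
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_metabolite(Metabolite("b_c", compartment="c"))
        m.add_reaction(
            Reaction("R", {"a_c": -1.0, "b_c": 1.0}, 0, 10, objective_coefficient=1.0)
        )
        m.biomass_reaction_id = "R"
        assert exchange_reactions(m) == []


class TestFBA:
    def test_uptake_cap_limits_growth(self, chain_model):
        # Yield 1 chain, uptake capped at 10 → analytic optimum 10.
        sol = fba(chain_model)
        assert sol.status is SolveStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_all_bounds_zero_gives_zero_growth(self, chain_model):
        for rxn in chain_model.reactions.values():
            rxn.lower_bound = rxn.upper_bound = 0.0
        sol = fba(chain_model)
        assert sol.status is SolveStatus.OPTIMAL
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_cycle_detected(self):
        m = MetabolicModel(id="unb")
        m.add_metabolite(Metabolite("x_c", compartment="c"))
        m.add_reaction(Reaction("MAKE", {"x_c": 1.0}, 0.0, math.inf))
        m.add_reaction(
            Reaction("BIO", {"x_c": -1.0}, 0.0, math.inf, objective_coefficient=1.0)
        )
        m.biomass_reaction_id = "BIO"
        sol = fba(m)
        assert sol.status is SolveStatus.UNBOUNDED
        assert sol.objective_value == 0.0
        assert sol.fluxes == {}

    def test_unknown_objective_reaction(self, chain_model):
        with pytest.raises(KeyError, match="unknown reaction"):
            fba(chain_model, {"missing": 1.0})

    def test_mass_balance_and_bounds_at_optimum(self, chain_model):
        sol = fba(chain_model)
        for rid, flux in sol.fluxes.items():
            rxn = chain_model.reactions[rid]
            assert rxn.lower_bound - FLUX_TOLERANCE <= flux <= rxn.upper_bound + FLUX_TOLERANCE
        balance: dict[str, float] = {}
        for rid, flux in sol.fluxes.items():
            for met, coef in chain_model.reactions[rid].stoichiometry.items():
                balance[met] = balance.get(met, 0.0) + coef * flux
        assert max(abs(v) for v in balance.values()) <= FLUX_TOLERANCE

    @pytest.mark.parametrize("kind", ["neutralism", "commensalism", "parasitism"])
    def test_agrees_with_vertex_enumeration_oracle(self, toy_pairs, kind):
        """On small fixture models the LP optimum must match brute force."""
        for model in toy_pairs[kind][:2]:
            sol = fba(model)
            expected = oracle_fba(model, {model.biomass_reaction_id: 1.0})
            assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_cobra_reads_our_sbml_and_agrees(self, toy_pairs, tmp_path):
        """COBRApy, as an independent constraint-based stack, must reproduce
        our growth optimum from the SBML we write."""
        import cobra.io

        from pairmint.diet_fba import apply_diet_to_model

        model_a, _, diet, _ = toy_pairs["parasitism"]
        dieted = apply_diet_to_model(model_a, diet)
        path = write_sbml(dieted, tmp_path / "dieted.xml")
        ours = fba(dieted).objective_value
        theirs = cobra.io.read_sbml_model(str(path)).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)
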