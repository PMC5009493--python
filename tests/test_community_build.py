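"""Two-species community construction: namespacing, lumen, silencing."""

import pytest

from pairmint.community_build import (
    CommunityModel,
    build_community,
    pair_list,
    namespace_model,
    silence_species,
)
from pairmint.diet_fba import apply_diet, apply_diet_to_model, community_growth
from pairmint.errors import CommunityBuildError, UnmatchedOTUError
from pairmint.model_core import fba
from pairmint.otu_prep import AssociationTable, GenomeMatch

from conftest import linear_chain_model


class TestPairList:
    MATCHES = [
        GenomeMatch("o1", "G1", 99.0),
        GenomeMatch("o2", "G2", 98.0),
        GenomeMatch("o3", "G1", 97.0),
    ]

    def test_association_rows_map_to_genome_pairs(self):
        assoc = AssociationTable([("o1", "o2", 0.9)])
        pairs = pair_list(assoc, self.MATCHES)
        assert pairs.pairs == [("G1", "G2")]
        assert pairs.otu_pairs == [("o1", "o2")]

    def test_same_genome_pair_dropped_with_warning(self, caplog):
        assoc = AssociationTable([("o1", "o3", 0.9)])  # both map to G1
        with caplog.at_level("WARNING"):
            pairs = pair_list(assoc, self.MATCHES)
        assert len(pairs) == 0
        assert "G1" in caplog.text

    def test_duplicate_genome_pairs_collapse(self):
        assoc = AssociationTable([("o1", "o2", 0.9), ("o3", "o2", 0.7)])
        pairs = pair_list(assoc, self.MATCHES)
        assert pairs.pairs == [("G1", "G2")]

    def test_unmatched_otu_is_an_error(self):
        assoc = AssociationTable([("o1", "oX", 0.9)])
        with pytest.raises(UnmatchedOTUError, match="oX"):
            pair_list(assoc, self.MATCHES)


class TestNamespacing:
    def test_ids_and_compartments_prefixed_consistently(self):
        model = linear_chain_model()
        ns, id_map = namespace_model(model, "A")
        assert set(ns.reactions) == {"A__EX_S", "A__T", "A__BIO"}
        assert ns.reactions["A__T"].stoichiometry == {"A__S_e": -1.0, "A__X_c": 1.0}
        assert ns.metabolites["A__S_e"].compartment == "A__e"
        assert id_map["T"] == "A__T"
        assert len(id_map) == len(model.reactions) + len(model.metabolites)

    def test_sizes_unchanged(self):
        model = linear_chain_model()
        ns, _ = namespace_model(model, "A")
        assert len(ns.reactions) == len(model.reactions)
        assert len(ns.metabolites) == len(model.metabolites)

    def test_double_namespacing_refused(self):
        ns, _ = namespace_model(linear_chain_model(), "A")
        with pytest.raises(ValueError, match="namespaced"):
            namespace_model(ns, "B")


class TestBuildCommunity:
    def test_shared_substrate_reaction_count(self):
        # 3 reactions each + 1 shared lumen metabolite → 7 reactions.
        com = build_community(linear_chain_model("a"), linear_chain_model("b"))
        assert len(com.base.reactions) == 7
        assert com.community_exchanges() == ["EX_S_u"]
        # The two species exchanges became lumen transports.
        assert com.base.reactions["A__EX_S"].stoichiometry == {
            "A__S_e": -1.0,
            "S_u": 1.0,
        }
        assert com.base.reactions["A__EX_S"].lower_bound == -1000.0

    def test_disjoint_substrates_two_lumen_metabolites(self, toy_pairs):
        a, b, _, _ = toy_pairs["neutralism"]
        com = build_community(a, b)
        assert len(com.community_exchanges()) == 2

    def test_tag_swap_symmetry_of_reaction_sets(self, toy_pairs):
        a, b, _, _ = toy_pairs["parasitism"]
        ab = build_community(a, b, "A", "B")
        ba = build_community(b, a, "A", "B")

        def canonical(com, flip):
            out = set()
            for rid, rxn in com.base.reactions.items():
                name = rid
                if flip:
                    name = name.replace("A__", "@").replace("B__", "A__").replace("@", "B__")
                out.add((name, rxn.lower_bound, rxn.upper_bound))
            return out

        assert canonical(ab, flip=False) == canonical(ba, flip=True)

    def test_model_without_exchanges_rejected(self):
        closed = linear_chain_model("closed")
        del closed.reactions["EX_S"]
        with pytest.raises(CommunityBuildError, match="exchange"):
            build_community(closed, linear_chain_model("b"))

    def test_identical_tags_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            build_community(linear_chain_model("a"), linear_chain_model("b"), "A", "A")

    def test_reaction_count_identity_all_fixtures(self, toy_pairs):
        for kind, (a, b, _, _) in toy_pairs.items():
            com = build_community(a, b)
            n_lumen = len(com.community_exchanges())
            assert len(com.base.reactions) == len(a.reactions) + len(b.reactions) + n_lumen, kind


class TestSilencing:
    def test_silenced_species_cannot_grow(self, toy_pairs):
        a, b, diet, _ = toy_pairs["neutralism"]
        com = apply_diet(build_community(a, b), diet)
        silenced = silence_species(com, "A")
        sol = fba(silenced.base, {com.biomass_ids["A"]: 1.0})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_partner_bounds_untouched(self, toy_pairs):
        a, b, _, _ = toy_pairs["neutralism"]
        com = build_community(a, b)
        silenced = silence_species(com, "A")
        for rid, rxn in com.base.reactions.items():
            if rid.startswith("B__") or rid.startswith("EX_"):
                assert silenced.base.reactions[rid].lower_bound == rxn.lower_bound
                assert silenced.base.reactions[rid].upper_bound == rxn.upper_bound

    def test_commensal_consumer_starves_without_producer(self, toy_pairs):
        a, b, diet, _ = toy_pairs["commensalism"]
        com = apply_diet(build_community(a, b), diet)
        silenced = silence_species(com, "A")
        sol = fba(silenced.base, {com.biomass_ids["B"]: 1.0})
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_tag_is_key_error(self, toy_pairs):
        a, b, _, _ = toy_pairs["neutralism"]
        with pytest.raises(KeyError, match="tag"):
            silence_species(build_community(a, b), "C")


class TestIsolationEquivalence:
    @pytest.mark.parametrize(
        "kind",
        ["neutralism", "competition", "commensalism", "mutualism", "parasitism", "amensalism"],
    )
    def test_silenced_partner_growth_equals_single_model_growth(self, toy_pairs, kind):
        """Growing 'alone' in the community equals growing the single-species
        model under the equivalent diet."""
        a, b, diet, _ = toy_pairs[kind]
        com = build_community(a, b)
        growth = community_growth(com, diet)
        for model, g_alone in ((a, growth.g_a_alone), (b, growth.g_b_alone)):
            single = fba(apply_diet_to_model(model, diet))
            assert g_alone == pytest.approx(single.objective_value, abs=1e-6)
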