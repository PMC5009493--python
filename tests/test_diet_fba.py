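"""Diets, diet application, and the four-growth-rate protocol."""

import pytest

from _oracles import oracle_fba
from pairmint.community_build import build_community
from pairmint.diet_fba import (
    Diet,
    GrowthResult,
    apply_diet,
    community_growth,
    read_diet,
    read_growth_results,
    scale_diet,
    write_diet,
    write_growth_results,
)
from pairmint.errors import FormatError


class TestDietIO:
    def test_read_two_rows(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("metabolite\tflux\nS_u\t10\nP_u\t5\n")
        diet = read_diet(path)
        assert diet.fluxes == {"S_u": 10.0, "P_u": 5.0}

    def test_negative_flux_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("metabolite\tflux\nS_u\t-1\n")
        with pytest.raises(FormatError, match="negative"):
            read_diet(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("S_u\t10\n")
        with pytest.raises(FormatError, match="header"):
            read_diet(path)

    def test_duplicate_metabolite_last_wins(self, tmp_path, caplog):
        path = tmp_path / "d.tsv"
        path.write_text("metabolite\tflux\nS_u\t10\nS_u\t3\n")
        with caplog.at_level("WARNING"):
            diet = read_diet(path)
        assert diet.fluxes["S_u"] == 3.0
        assert "duplicate" in caplog.text

    def test_round_trip(self, tmp_path):
        diet = Diet("d", {"S_u": 12.5, "P_u": 0.0})
        back = read_diet(write_diet(diet, tmp_path / "d.tsv"))
        assert back.fluxes == diet.fluxes

    def test_packaged_complete_diet_all_fluxes_100(self, toy_study_dir):
        diet = read_diet(toy_study_dir / "diets" / "complete.tsv")
        assert diet.fluxes  # non-empty
        assert all(v == 100.0 for v in diet.fluxes.values())


class TestScaleDiet:
    def test_variant_1_is_ten_times_slower(self):
        diet = Diet("complete", {"S_u": 100.0})
        assert scale_diet(diet, 0.1).fluxes["S_u"] == pytest.approx(10.0)

    def test_variant_2_is_hundred_times_slower(self):
        diet = Diet("complete", {"S_u": 100.0})
        assert scale_diet(diet, 0.01).fluxes["S_u"] == pytest.approx(1.0)

    def test_identity_factor(self):
        diet = Diet("d", {"S_u": 7.0})
        assert scale_diet(diet, 1.0).fluxes == diet.fluxes

    def test_name_records_the_division(self):
        assert scale_diet(Diet("complete", {}), 0.1).name == "complete/10"

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_diet(Diet("d", {}), 0.0)


class TestApplyDiet:
    def test_listed_metabolite_opens_uptake_others_closed(self, toy_pairs):
        a, b, _, _ = toy_pairs["commensalism"]
        com = build_community(a, b)
        dieted = apply_diet(com, Diet("d", {"cms_S_u": 10.0}))
        ex_s = dieted.base.reactions["EX_cms_S_u"]
        ex_p = dieted.base.reactions["EX_cms_P_u"]
        assert (ex_s.lower_bound, ex_s.upper_bound) == (-10.0, 1000.0)
        assert (ex_p.lower_bound, ex_p.upper_bound) == (0.0, 1000.0)

    def test_empty_diet_closes_all_uptake(self, toy_pairs):
        a, b, _, _ = toy_pairs["neutralism"]
        dieted = apply_diet(build_community(a, b), Diet("nothing", {}))
        for rid in dieted.community_exchanges():
            assert dieted.base.reactions[rid].lower_bound == 0.0

    def test_unknown_diet_metabolite_skipped(self, toy_pairs, caplog):
        a, b, _, _ = toy_pairs["neutralism"]
        com = build_community(a, b)
        with caplog.at_level("INFO"):
            dieted = apply_diet(com, Diet("d", {"nonexistent_u": 5.0}))
        assert "nonexistent_u" in caplog.text
        # Original community untouched (apply_diet copies).
        assert com.base.reactions["EX_neu_S1_u"].lower_bound == -1000.0
        assert dieted.base.reactions["EX_neu_S1_u"].lower_bound == 0.0


class TestCommunityGrowth:
    def test_neutral_pair_grows_identically_alone_and_together(self, toy_pairs):
        a, b, diet, _ = toy_pairs["neutralism"]
        g = community_growth(build_community(a, b), diet)
        assert (g.g_a_alone, g.g_a_together, g.g_b_alone, g.g_b_together) == (
            pytest.approx(10.0),
            pytest.approx(10.0),
            pytest.approx(10.0),
            pytest.approx(10.0),
        )

    def test_commensal_consumer_needs_its_producer(self, toy_pairs):
        a, b, diet, _ = toy_pairs["commensalism"]
        g = community_growth(build_community(a, b), diet)
        assert g.g_b_alone == 0.0
        assert g.g_b_together == pytest.approx(10.0)
        assert g.g_a_alone == pytest.approx(10.0)
        assert g.g_a_together == pytest.approx(10.0)

    def test_competitors_split_the_substrate_fairly(self, toy_pairs):
        a, b, diet, _ = toy_pairs["competition"]
        g = community_growth(build_community(a, b), diet, degeneracy="fair")
        assert g.g_a_together == pytest.approx(5.0, abs=1e-6)
        assert g.g_b_together == pytest.approx(5.0, abs=1e-6)

    def test_vertex_mode_preserves_the_joint_total(self, toy_pairs):
        a, b, diet, _ = toy_pairs["competition"]
        g = community_growth(build_community(a, b), diet, degeneracy="vertex")
        assert g.g_a_together + g.g_b_together == pytest.approx(10.0, abs=1e-6)

    def test_joint_total_matches_joint_lp_optimum(self, toy_pairs):
        """Degeneracy resolution must not change the joint optimum."""
        for kind, (a, b, diet, _) in toy_pairs.items():
            com = build_community(a, b)
            dieted = apply_diet(com, diet)
            expected = oracle_fba(
                dieted.base,
                {com.biomass_ids["A"]: 1.0, com.biomass_ids["B"]: 1.0},
            )
            g = community_growth(com, diet)
            assert g.g_a_together + g.g_b_together == pytest.approx(
                expected, abs=1e-6
            ), kind

    def test_diet_monotonicity(self, toy_pairs):
        """Scaling a diet down never increases the joint optimum."""
        for kind, (a, b, diet, _) in toy_pairs.items():
            com = build_community(a, b)
            totals = []
            for factor in (1.0, 0.1, 0.01):
                g = community_growth(com, scale_diet(diet, factor))
                totals.append(g.g_a_together + g.g_b_together)
            assert totals[0] >= totals[1] - 1e-9, kind
            assert totals[1] >= totals[2] - 1e-9, kind

    def test_rates_never_in_the_clamp_window(self, toy_pairs):
        for kind, (a, b, diet, _) in toy_pairs.items():
            g = community_growth(build_community(a, b), diet)
            for v in (g.g_a_alone, g.g_a_together, g.g_b_alone, g.g_b_together):
                assert v == 0.0 or v >= 1e-9

    def test_negative_rate_rejected_by_container(self):
        with pytest.raises(ValueError):
            GrowthResult(("a", "b"), -1.0, 0.0, 0.0, 0.0)


def test_growth_table_round_trip(tmp_path):
    results = [GrowthResult(("G1", "G2"), 10.0, 15.0, 10.0, 5.0)]
    back = read_growth_results(write_growth_results(results, tmp_path / "g.tsv"))
    assert back[0].pair == ("G1", "G2")
    assert back[0].g_a_together == 15.0
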