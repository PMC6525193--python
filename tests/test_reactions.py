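"""Bioenergetic stoichiometry: balance, yields, groups and scenarios."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soursim.chem import UnknownSpeciesError, mg_per_l_to_mol_per_l, species
from soursim.reactions import (
    BALANCE_TOL,
    GROUPS,
    HALF_REACTIONS,
    BalanceError,
    CommunityReaction,
    check_balance,
    combine_half_reactions,
    enumerate_scenarios,
    half_reaction_residuals,
    is_admissible,
    stoich_yield,
)


def combine(donor, acceptor, fe):
    return combine_half_reactions(
        HALF_REACTIONS[donor], HALF_REACTIONS[acceptor], HALF_REACTIONS["cell_synthesis"], fe
    )


class TestHalfReactions:
    def test_inventory_is_balanced(self):
        for hr in HALF_REACTIONS.values():
            res = half_reaction_residuals(hr)
            assert max(abs(v) for v in res.values()) < BALANCE_TOL, hr.id

    def test_electron_equivalents_match_reference_coefficients(self):
        # per e-eq, the reference species coefficient must be 1/e_eq
        for hr in HALF_REACTIONS.values():
            c = abs(hr.stoich[hr.reference_species])
            assert c == pytest.approx(1.0 / hr.e_eq_per_mole)


class TestCombine:
    def test_all_communities_balance(self, communities):
        for name, rxn in communities.items():
            res = check_balance(rxn)
            assert max(abs(v) for v in res.values()) < BALANCE_TOL, name

    def test_srb_sulfate_lactate_yield(self, communities):
        # 12 e-eq lactate donor, 8 e-eq sulfate acceptor, fe = 0.8499
        assert stoich_yield(communities["SRB"], "sulfate", "lactate") == pytest.approx(
            1.2748, abs=1e-3
        )

    def test_nrsob_direct_and_indirect_sulfide_yields(self, communities):
        direct = stoich_yield(communities["NRSOB1"], "sulfide", "nitrate")
        indirect = stoich_yield(communities["NRSOB2"], "sulfide", "nitrite")
        assert direct == pytest.approx(2.0 / (8.0 * 0.8623))
        assert indirect == pytest.approx(0.8665, abs=1e-3)
        # nitrate step produces exactly one nitrite per nitrate
        assert stoich_yield(communities["NRSOB1"], "nitrite", "nitrate") == pytest.approx(1.0)

    @given(fe=st.floats(0.05, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_srb_yield_closed_form_in_fe(self, fe):
        rxn = combine("lactate_oxidation", "sulfate_reduction", fe)
        assert stoich_yield(rxn, "sulfate", "lactate") == pytest.approx(12.0 * fe / 8.0)
        res = check_balance(rxn)
        assert max(abs(v) for v in res.values()) < BALANCE_TOL

    def test_fe_one_limit_is_pure_redox(self):
        rxn = combine("lactate_oxidation", "sulfate_reduction", 1.0)
        assert "biomass" not in rxn.stoich
        assert stoich_yield(rxn, "sulfate", "lactate") == pytest.approx(1.5)
        # normalized per mole donor
        assert rxn.stoich["lactate"] == pytest.approx(-1.0)

    def test_fe_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fe"):
            combine("lactate_oxidation", "sulfate_reduction", 1.2)
        with pytest.raises(ValueError, match="fe"):
            combine("lactate_oxidation", "sulfate_reduction", 0.0)

    def test_role_mismatch_rejected(self):
        with pytest.raises(ValueError, match="not a donor"):
            combine_half_reactions(
                HALF_REACTIONS["sulfate_reduction"],
                HALF_REACTIONS["sulfate_reduction"],
                HALF_REACTIONS["cell_synthesis"],
                0.8,
            )


class TestBalanceChecks:
    def test_perturbed_coefficient_is_flagged(self, communities):
        rxn = communities["SRB"]
        bad = CommunityReaction(
            name="bad",
            donor_species=rxn.donor_species,
            acceptor_species=rxn.acceptor_species,
            fe=rxn.fe,
            stoich={**rxn.stoich, "sulfate": rxn.stoich["sulfate"] + 0.1},
        )
        res = check_balance(bad)
        assert abs(res["S"]) > 1e-3

    def test_unknown_species_raises(self, communities):
        rxn = communities["SRB"]
        bad = CommunityReaction("bad", "x", "y", 0.9, {"unobtainium": 1.0})
        with pytest.raises(UnknownSpeciesError):
            check_balance(bad)

    def test_stoich_yield_identity_and_missing_species(self, communities):
        srb = communities["SRB"]
        assert stoich_yield(srb, "sulfate", "sulfate") == 1.0
        with pytest.raises(KeyError):
            stoich_yield(srb, "nitrate", "sulfate")


class TestScenarios:
    def test_full_enumeration_is_eleven_plus_three(self):
        scenarios = enumerate_scenarios()
        assert len(scenarios) == 14
        dnra = [s for s in scenarios if s.groups[0] in "ABCD"]
        denit = [s for s in scenarios if s.groups[0] in "EF"]
        assert (len(dnra), len(denit)) == (11, 3)

    def test_family_restrictions(self):
        assert len(enumerate_scenarios(families=("denitrification",))) == 3
        assert len(enumerate_scenarios(families=("DNRA",))) == 11

    def test_dnra_count_by_brute_force(self):
        # all 15 non-empty subsets of {A,B,C,D} minus the 4 with D but not C
        import itertools

        subsets = [
            s
            for r in range(1, 5)
            for s in itertools.combinations("ABCD", r)
        ]
        admissible = [s for s in subsets if not ("D" in s and "C" not in s)]
        assert len(subsets) == 15
        assert len(admissible) == 11
        assert [s.groups for s in enumerate_scenarios(families=("DNRA",))] == sorted(admissible)

    def test_every_scenario_satisfies_admissibility(self):
        for sc in enumerate_scenarios():
            assert is_admissible(sc.groups)
            fams = {GROUPS[g].pathway for g in sc.groups}
            assert len(fams) == 1
            if "D" in sc.groups:
                assert "C" in sc.groups

    def test_enumeration_is_stable(self):
        a = [s.groups for s in enumerate_scenarios()]
        b = [s.groups for s in enumerate_scenarios()]
        assert a == b

    def test_group_pairs_share_a_donor(self, communities):
        for g in GROUPS.values():
            d1 = communities[g.nitrate_step].donor_species
            d2 = communities[g.nitrite_step].donor_species
            if g.sulfur_role == "S0->sulfate":
                assert d1 == d2 == "sulfur"
            else:
                assert d1 == d2


class TestUnits:
    def test_sulfate_molar_mass_conversion(self):
        assert mg_per_l_to_mol_per_l(96.06, "sulfate") == pytest.approx(1e-3)

    def test_conversion_round_trip(self):
        from soursim.chem import from_mol_per_l, to_mol_per_l

        for unit in ("mg/l", "mM", "mol/l"):
            v = to_mol_per_l(123.4, unit, "nitrate")
            assert from_mol_per_l(v, unit, "nitrate") == pytest.approx(123.4, rel=1e-12)
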