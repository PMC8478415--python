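"""Pedigree validation: harmonization, loops, disconnection, pseudo-parents."""

import numpy as np
import pytest

from panelped import (
    CancerHistory, Individual, LoopError, Pedigree, PedigreeError,
    add_pseudo_parents, brute_force_posterior, check_pedigree, detect_loops,
    remove_disconnected,
)
from conftest import nuclear_family


def _ped(members, cancers=("BC", "OC")):
    for m in members:
        for c in cancers:
            m.cancers.setdefault(c, CancerHistory())
    return Pedigree.from_members(members, cancers=list(cancers))


class TestHeredityHarmonization:
    def test_child_conflicting_with_both_parents_reset(self, toy_db):
        ped = nuclear_family()
        ped[1].ancestry = "AJ"
        ped[2].ancestry = "AJ"
        ped[3].ancestry = "Italian"  # conflicts with both parents
        out, report = check_pedigree(ped, toy_db)
        assert out[3].ancestry == "nonAJ"
        assert any("has been changed to nonAJ to meet heredity consistency" in m
                   for m in report.messages)
        assert 3 in report.changed_ids["heredity_ancestry"]

    def test_race_conflict_reset_to_all_races(self, toy_db):
        ped = nuclear_family()
        ped[1].race = "White"
        ped[2].race = "White"
        ped[4].race = "Asian"
        out, report = check_pedigree(ped, toy_db)
        assert out[4].race == "All_Races"
        assert any("has been changed to All_Races" in m for m in report.messages)

    def test_child_matching_one_parent_untouched(self, toy_db):
        ped = nuclear_family()
        ped[1].ancestry = "AJ"
        ped[2].ancestry = "nonAJ"
        ped[3].ancestry = "AJ"
        out, _ = check_pedigree(ped, toy_db)
        assert out[3].ancestry == "AJ"

    def test_consistent_pedigree_is_fixed_point(self, toy_db):
        ped = nuclear_family()
        out, report = check_pedigree(ped, toy_db)
        # pseudo-parent insertion is the only structural change possible here
        assert report.changed_ids.keys() <= {"added_pseudo_parents"}
        again, report2 = check_pedigree(out, toy_db)
        assert {m.id: m for m in again} == {m.id: m for m in out}
        assert "heredity_ancestry" not in report2.changed_ids

    def test_idempotence_after_repairs(self, toy_db):
        ped = nuclear_family()
        ped[1].ancestry = "AJ"
        ped[2].ancestry = "AJ"
        ped[3].ancestry = "Italian"
        ped[5].cur_age = 94
        once, _ = check_pedigree(ped, toy_db)
        twice, report2 = check_pedigree(once, toy_db)
        assert {m.id: m for m in twice} == {m.id: m for m in once}
        assert not any(k.startswith("heredity") for k in report2.changed_ids)


class TestErrors:
    def test_no_proband_rejected(self, toy_db):
        ped = nuclear_family()
        for m in ped:
            m.is_proband = 0
        with pytest.raises(PedigreeError, match="proband"):
            check_pedigree(ped, toy_db)

    def test_male_with_female_only_cancer_rejected(self, toy_db):
        ped = nuclear_family()
        ped[4].cancers["OC"] = CancerHistory(affected=1, diagnosis_age=35)
        with pytest.raises(PedigreeError, match="Ovarian"):
            check_pedigree(ped, toy_db)

    def test_diagnosis_after_censoring_rejected(self, toy_db):
        ped = nuclear_family()
        ped[3].cancers["BC"] = CancerHistory(affected=1, diagnosis_age=60)
        with pytest.raises(PedigreeError, match="exceeds CurAge"):
            check_pedigree(ped, toy_db)

    def test_twins_with_different_sex_rejected(self, toy_db):
        ped = nuclear_family(child_sexes=(0, 1, 1))
        ped[3].twin_group = 1
        ped[4].twin_group = 1
        with pytest.raises(PedigreeError, match="twin"):
            check_pedigree(ped, toy_db)

    def test_age_above_axis_clamped_with_warning(self, toy_db):
        ped = nuclear_family()
        ped[1].cur_age = 99  # type: ignore[assignment]
        ped[1].cur_age = 99
        with pytest.warns(UserWarning, match="clamped"):
            out, report = check_pedigree(ped, toy_db)
        assert out[1].cur_age == 94
        assert 1 in report.changed_ids["age_clamped"]

    def test_germline_resolution_message(self, toy_db):
        ped = nuclear_family()
        ped[3].germline["BRCA1"] = 0
        _, report = check_pedigree(ped, toy_db)
        assert any("BRCA1_hetero_anyPV" in m and "Germline" in m
                   for m in report.messages)


class TestLoops:
    def test_nuclear_family_has_no_loop(self):
        assert detect_loops(nuclear_family()) == []

    def test_cross_sibling_mating_is_a_loop(self, toy_db):
        # two sibling pairs from two families intermarry: a marriage-node loop
        members = [
            Individual(id=1, sex=0, cur_age=90), Individual(id=2, sex=1, cur_age=90),
            Individual(id=3, sex=0, cur_age=88), Individual(id=4, sex=1, cur_age=88),
            # family A siblings (brother 5, sister 6); family B siblings (7, 8)
            Individual(id=5, sex=1, mother_id=1, father_id=2, cur_age=59),
            Individual(id=6, sex=0, mother_id=1, father_id=2, cur_age=55),
            Individual(id=7, sex=0, mother_id=3, father_id=4, cur_age=60),
            Individual(id=8, sex=1, mother_id=3, father_id=4, cur_age=62),
            # cross marriages: 5x7 and 8x6, each with a child
            Individual(id=9, sex=0, mother_id=7, father_id=5, cur_age=30, is_proband=1),
            Individual(id=10, sex=1, mother_id=6, father_id=8, cur_age=28),
        ]
        ped = _ped(members)
        loops = detect_loops(ped)
        assert len(loops) == 1
        assert {5, 6, 7, 8} <= set(loops[0])
        with pytest.raises(LoopError):
            check_pedigree(ped, toy_db)

    def test_first_cousin_mating_loops_through_grandparents(self):
        members = [
            Individual(id=1, sex=0, cur_age=90), Individual(id=2, sex=1, cur_age=90),
            Individual(id=3, sex=0, mother_id=1, father_id=2, cur_age=60),
            Individual(id=4, sex=1, mother_id=1, father_id=2, cur_age=58),
            Individual(id=5, sex=1, cur_age=62),  # spouse of 3
            Individual(id=6, sex=0, cur_age=57),  # spouse of 4
            Individual(id=7, sex=1, mother_id=3, father_id=5, cur_age=35),
            Individual(id=8, sex=0, mother_id=6, father_id=4, cur_age=33),
            Individual(id=9, sex=0, mother_id=8, father_id=7, cur_age=10,
                       is_proband=1),
        ]
        loops = detect_loops(_ped(members))
        assert len(loops) == 1
        assert {1, 2} <= set(loops[0])  # shared grandparents on the cycle


class TestRemoveDisconnected:
    def test_isolated_individual_removed(self):
        ped = nuclear_family()
        ped.individuals[99] = Individual(id=99, sex=0, cur_age=50, cancers={
            "BC": CancerHistory(), "OC": CancerHistory()})
        out, removed = remove_disconnected(ped)
        assert removed == [99]
        assert 99 not in out.individuals

    def test_connected_pedigree_untouched(self):
        ped = nuclear_family()
        out, removed = remove_disconnected(ped)
        assert removed == [] and len(out) == len(ped)

    def test_removal_preserves_proband_posterior(self, toy_db, toy_mdb, toy_space):
        ped = nuclear_family()
        ped.individuals[99] = Individual(
            id=99, sex=0, cur_age=44,
            cancers={"BC": CancerHistory(affected=1, diagnosis_age=40),
                     "OC": CancerHistory()})
        trimmed, removed = remove_disconnected(ped)
        assert removed == [99]
        full = brute_force_posterior(ped, toy_mdb, toy_space)
        trim = brute_force_posterior(trimmed, toy_mdb, toy_space)
        np.testing.assert_allclose(full.probands[3]["estimate"],
                                   trim.probands[3]["estimate"], atol=1e-12)

    def test_singleton_proband_warns(self, toy_db):
        solo = Pedigree.from_members([
            Individual(id=1, sex=0, is_proband=1, cur_age=40,
                       cancers={"BC": CancerHistory()})], cancers=["BC"])
        with pytest.warns(UserWarning, match="singleton"):
            out, _ = check_pedigree(solo, toy_db)
        assert len(out) == 1


class TestPseudoParents:
    def test_mother_only_child_gets_pseudo_father(self):
        members = [
            Individual(id=1, sex=0, cur_age=70, ancestry="AJ", race="White"),
            Individual(id=2, sex=0, mother_id=1, cur_age=40, is_proband=1),
        ]
        ped = _ped(members, cancers=("BC",))
        out, added = add_pseudo_parents(ped)
        assert len(added) == 1
        pseudo = out.individuals[added[0]]
        assert pseudo.sex == 1 and pseudo.pseudo
        assert pseudo.ancestry == "AJ" and pseudo.race == "White"
        assert pseudo.cur_age is None and pseudo.is_founder()
        assert out[2].father_id == added[0]

    def test_siblings_share_one_pseudo_parent(self):
        members = [
            Individual(id=1, sex=0, cur_age=70),
            Individual(id=2, sex=0, mother_id=1, cur_age=40, is_proband=1),
            Individual(id=3, sex=1, mother_id=1, cur_age=38),
        ]
        out, added = add_pseudo_parents(_ped(members, cancers=("BC",)))
        assert len(added) == 1
        assert out[2].father_id == out[3].father_id == added[0]

    def test_two_parent_children_unchanged(self):
        ped = nuclear_family()
        out, added = add_pseudo_parents(ped)
        assert added == []
        assert {m.id: m for m in out} == {m.id: m for m in ped}

    def test_chain_of_single_parents(self):
        members = [
            Individual(id=1, sex=0, cur_age=90),
            Individual(id=2, sex=0, mother_id=1, cur_age=65),
            Individual(id=3, sex=0, mother_id=2, cur_age=40, is_proband=1),
        ]
        out, added = add_pseudo_parents(_ped(members, cancers=("BC",)))
        assert len(added) == 2
        assert len({m.id for m in out}) == 5

    def test_check_output_has_two_parents_everywhere_and_no_loops(self, toy_db):
        members = [
            Individual(id=1, sex=0, cur_age=70),
            Individual(id=2, sex=0, mother_id=1, cur_age=40, is_proband=1),
        ]
        out, _ = check_pedigree(_ped(members, cancers=("BC",)), toy_db)
        for m in out:
            assert (m.mother_id is None) == (m.father_id is None)
        assert detect_loops(out) == []
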