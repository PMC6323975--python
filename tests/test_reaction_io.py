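"""Parsing, validation, cofactor lists and run policies."""

import pytest
from hypothesis import given, settings, strategies as st

import ruleforge as rf
from ruleforge.errors import (CofactorFileError, MappingError, PolicyError,
                              ReactionParseError)
from ruleforge.reaction_io import read_reactions_tsv, write_reactions_tsv


class TestParsing:
    def test_minimal_reaction(self):
        rxn = rf.parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][O-:2]", "r1")
        assert len(rxn.substrates) == 1 and len(rxn.products) == 1
        assert rxn.side_maps("substrates") == rxn.side_maps("products") == {1, 2}

    def test_multi_substrate_shared_maps(self):
        rxn = rf.parse_mapped_reaction(
            "[C:1](=[O:2])C.[NH3:3]>>[C:1](=[NH:3])C.[OH2:2]", "r2")
        assert len(rxn.substrates) == 2 and len(rxn.products) == 2
        assert rxn.side_maps("substrates") == {1, 2, 3}

    def test_duplicate_map_on_one_side_rejected(self):
        with pytest.raises(MappingError):
            rf.parse_mapped_reaction(
                "[CH3:1][OH:2].[CH3:1]O>>[CH3:1][O-:2]", "r3")

    @pytest.mark.parametrize("bad", ["CCO", "C>>C>>C", "not-a-smiles>>C", "C>>"])
    def test_malformed_strings(self, bad):
        with pytest.raises(ReactionParseError):
            rf.parse_mapped_reaction(bad, "bad")

    def test_stoichiometry_aggregation(self):
        rxn = rf.parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][O-:2].O.O", "r4")
        water = [sp for sp in rxn.products if sp.molecule.canonical_smiles() == "O"]
        assert len(water) == 1 and water[0].count == 2

    def test_round_trip(self, corpus):
        for rxn in corpus.reactions:
            text = rxn.to_string()
            again = rf.parse_mapped_reaction(text, rxn.reaction_id)
            assert again.to_string() == text

    @settings(deadline=None, max_examples=30)
    @given(n=st.integers(2, 6), data=st.data())
    def test_round_trip_generated_chains(self, n, data):
        """Parse -> serialise -> parse is stable on generated mapped alkanols."""
        maps = data.draw(st.permutations(list(range(1, n + 1))))
        atoms = [f"[CH3:{maps[0]}]"] + [f"[CH2:{m}]" for m in maps[1:-1]] + [f"[OH:{maps[-1]}]"]
        sub = "".join(atoms)
        prod = sub.replace(f"[OH:{maps[-1]}]", f"[O-:{maps[-1]}]")
        rxn = rf.parse_mapped_reaction(f"{sub}>>{prod}", "gen")
        assert rf.parse_mapped_reaction(rxn.to_string(), "gen").to_string() == rxn.to_string()


class TestValidation:
    def test_transport_is_no_change(self, strict_policy):
        rxn = rf.parse_mapped_reaction("[OH2:1]>>[OH2:1]", "t")
        verdict = rf.validate_reaction(rxn, strict_policy)
        assert not verdict.accepted and verdict.reason == "no-change"

    def test_r_group_is_underspecified(self, strict_policy):
        rxn = rf.parse_mapped_reaction("[*:1][CH2:2][OH:3]>>[*:1][CH:2]=[O:3]", "r")
        assert rf.validate_reaction(rxn, strict_policy).reason == "underspecified"

    def test_unbalanced_strict_vs_diy(self, strict_policy, diy_policy):
        rxn = rf.parse_mapped_reaction("[CH3:1][CH3:2]>>[CH4:1]", "u")
        assert rf.validate_reaction(rxn, strict_policy).reason == "unbalanced"
        assert rf.validate_reaction(rxn, diy_policy).accepted

    def test_charge_imbalance_is_warning_not_rejection(self, diy_policy):
        rxn = rf.parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][O-:2]", "q")
        verdict = rf.validate_reaction(rxn, diy_policy)
        assert verdict.accepted and any("charge" in w for w in verdict.warnings)

    def test_verdict_is_pure(self, corpus, strict_policy):
        for rxn in corpus.reactions:
            assert (rf.validate_reaction(rxn, strict_policy)
                    == rf.validate_reaction(rxn, strict_policy))

    def test_balanced_verdicts_agree_across_modes(self, corpus, strict_policy, diy_policy):
        """Strict and DIY verdicts only diverge through the balance check."""
        for rxn in corpus.reactions:
            strict = rf.validate_reaction(rxn, strict_policy)
            diy = rf.validate_reaction(rxn, diy_policy)
            if strict.reason != "unbalanced":
                assert strict.reason == diy.reason

    def test_racemization_accepted_only_with_stereo(self, corpus, strict_policy,
                                                    stereo_policy):
        rxn = corpus.reaction(corpus.racemization_id)
        assert rf.validate_reaction(rxn, strict_policy).reason == "no-change"
        assert rf.validate_reaction(rxn, stereo_policy).accepted


class TestCofactors:
    def test_load_dedup_and_comments(self, tmp_path):
        path = tmp_path / "cof.smi"
        path.write_text("O\nO=C=O  # carbon dioxide\n\nO\n# comment line\n")
        cof = rf.load_cofactors(path)
        assert len(cof) == 2

    def test_membership_ignores_maps(self, tmp_path):
        path = tmp_path / "cof.smi"
        path.write_text("O\n")
        cof = rf.load_cofactors(path)
        assert rf.MappedMolecule.from_smiles("[OH2:7]") in cof
        assert rf.MappedMolecule.from_smiles("[CH4:1]") not in cof

    def test_unparseable_entry_names_line(self, tmp_path):
        path = tmp_path / "cof.smi"
        path.write_text("O\nnot_a_smiles\n")
        with pytest.raises(CofactorFileError, match=":2"):
            rf.load_cofactors(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "cof.smi"
        path.write_text("")
        assert len(rf.load_cofactors(path)) == 0

    def test_default_list_contains_water_and_atp(self):
        cof = rf.CofactorList.default()
        assert rf.MappedMolecule.from_smiles("O") in cof
        assert rf.MappedMolecule.from_smiles(
            "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O") in cof


class TestRunPolicy:
    def test_diy_forces_no_cofactor_removal(self):
        policy = rf.RunPolicy(mode="diy", cofactor_removal=True)
        assert policy.cofactor_removal is False

    def test_diameters_sorted_deduped_max_last(self):
        policy = rf.RunPolicy(diameters=(8, 2, "max", 2, 0))
        assert policy.diameters == (0, 2, 8, None)

    @pytest.mark.parametrize("bad", [(3,), (-2,), (1, 2)])
    def test_invalid_diameters(self, bad):
        with pytest.raises(PolicyError):
            rf.RunPolicy(diameters=bad)

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "policy.yaml"
        path.write_text("mode: diy\nstereo_enabled: true\ndiameters: [4, 2]\n")
        policy = rf.RunPolicy.from_yaml(path)
        assert policy.mode == "diy" and policy.stereo_enabled
        assert policy.diameters == (2, 4)


class TestTsv:
    def test_write_read_round_trip(self, corpus, tmp_path):
        path = tmp_path / "reactions.tsv"
        write_reactions_tsv(corpus.reactions, path)
        records = read_reactions_tsv(path)
        assert [r.reaction_id for r in records] == [r.reaction_id for r in corpus.reactions]
        parsed = {r.reaction_id: r.reaction for r in records}
        for rxn in corpus.reactions:
            assert parsed[rxn.reaction_id].to_string() == rxn.to_string()
            assert parsed[rxn.reaction_id].ec_numbers == rxn.ec_numbers
            assert parsed[rxn.reaction_id].sequence_ids == rxn.sequence_ids

    def test_missing_structure_becomes_failed_record(self, tmp_path):
        path = tmp_path / "reactions.tsv"
        path.write_text("R1\t\nR2\tgarbage>>smiles\nR3\t[CH4:1]>>[CH4:1]\n")
        records = read_reactions_tsv(path)
        assert records[0].reaction is None and records[1].reaction is None
        assert records[2].reaction is not None
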