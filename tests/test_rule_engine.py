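"""Decomposition, rule extraction, canonicalisation and application."""

import pytest
from rdkit import Chem

import ruleforge as rf
from ruleforge.errors import DiameterError, NoPrimarySubstrateError
from conftest import ALL_DIAMETERS, component_index, component_products


def hpp_forward_rules(result, corpus):
    hpp_id = corpus.reaction("TRANS1").substrates[0].molecule.canonical_smiles()
    return {r.diameter: r for r in result.rules
            if r.reaction_id == "TRANS1" and r.substrate_id == hpp_id}


class TestDecompose:
    def test_component_counts_match_expectations(self, corpus, nonstereo_result):
        from collections import Counter
        counts = Counter(c.parent_reaction_id for c in nonstereo_result.components)
        for rid, exp in corpus.expected.items():
            if exp.verdict_nonstereo == "ok":
                assert counts[rid] == exp.n_components, rid

    def test_component_count_law(self, corpus, nonstereo_result, cofactors):
        """#components = #non-cofactor substrates + #non-cofactor products."""
        from collections import Counter
        counts = Counter(c.parent_reaction_id for c in nonstereo_result.components)
        for rid in nonstereo_result.accepted_ids:
            rxn = corpus.reaction(rid)
            expected = sum(1 for sp in rxn.substrates if sp.molecule not in cofactors)
            expected += sum(1 for sp in rxn.products if sp.molecule not in cofactors)
            assert counts[rid] == expected

    def test_water_never_seeds_a_component(self, nonstereo_result):
        assert all(c.substrate.canonical_smiles() != "O"
                   for c in nonstereo_result.components)

    def test_hydrolysis_cofactor_logged(self, nonstereo_result):
        hydro = [c for c in nonstereo_result.components
                 if c.parent_reaction_id == "HYDRO1"]
        assert len(hydro) == 2
        reverse = [c for c in hydro if c.direction == "reverse"][0]
        assert reverse.removed_cofactors == ("O",)

    def test_diy_all_species_primary(self, corpus, diy_result):
        """In DIY mode water seeds components like any other species."""
        hydro = [c for c in diy_result.components if c.parent_reaction_id == "HYDRO1"]
        assert len(hydro) == 3
        assert any(c.substrate.canonical_smiles() == "O" for c in hydro)

    def test_all_cofactor_substrates_is_an_error(self, strict_policy, cofactors):
        rxn = rf.parse_mapped_reaction(
            "[O:1]=[C:2]=[O:3].[OH2:4]>>[O:1]=[C:2]([OH:3])[OH:4]", "caco3")
        center = rf.identify_reaction_center(rxn)
        with pytest.raises(NoPrimarySubstrateError):
            rf.decompose(rxn, center, cofactors, strict_policy)

    def test_products_share_an_atom_with_the_substrate(self, nonstereo_result):
        for comp in nonstereo_result.components:
            for mol, _ in comp.products:
                assert comp.substrate.map_numbers & mol.map_numbers


class TestExtract:
    @pytest.mark.parametrize("bad", [3, -2, 1.5])
    def test_invalid_diameter(self, bad, nonstereo_result):
        with pytest.raises(DiameterError):
            rf.extract_rule(nonstereo_result.components[0], bad, False)

    def test_diameter_zero_keeps_only_reacting_atoms(self, corpus, nonstereo_result):
        rule = hpp_forward_rules(nonstereo_result, corpus)[0]
        sub_frag = rule._frags[0]
        assert sub_frag.GetNumAtoms() == 2  # the keto carbon and oxygen
        assert {a.GetIntProp("_origMap") for a in sub_frag.GetAtoms()} == {7, 8}

    def test_substrate_atom_sets_nest_with_diameter(self, corpus, nonstereo_result):
        rules = hpp_forward_rules(nonstereo_result, corpus)
        previous = set()
        for d in ALL_DIAMETERS:
            atoms = {a.GetIntProp("_origMap") for a in rules[d]._frags[0].GetAtoms()}
            assert previous <= atoms
            previous = atoms

    def test_determinism(self, corpus, cofactors, strict_policy):
        runs = []
        for _ in range(2):
            rxn = corpus.reaction("ESTER1")
            comps = rf.decompose(rxn, rf.identify_reaction_center(rxn),
                                 cofactors, strict_policy)
            runs.append(sorted(rf.extract_rule(c, 4, False).rule_smarts for c in comps))
        assert runs[0] == runs[1]

    def test_atom_order_permutation_invariance(self, cofactors, strict_policy):
        """Re-writing the input SMILES in another atom order changes nothing."""
        variants = [
            "[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][CH2:6][OH:7]"
            ">>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5].[OH2:4]",
            "[OH:7][CH2:6][CH3:5].[C:2]([CH3:1])(=[O:3])[OH:4]"
            ">>[OH2:4].[C:2]([CH3:1])(=[O:3])[O:7][CH2:6][CH3:5]",
        ]
        outputs = []
        for text in variants:
            rxn = rf.parse_mapped_reaction(text, "perm")
            comps = rf.decompose(rxn, rf.identify_reaction_center(rxn),
                                 cofactors, strict_policy)
            outputs.append(sorted((rf.extract_rule(c, d, False).rule_smarts,
                                   rf.extract_rule(c, d, False).rule_smiles)
                                  for c in comps for d in (0, 2, None)))
        assert outputs[0] == outputs[1]

    def test_canonicalize_idempotent(self, nonstereo_result):
        for rule in nonstereo_result.rules[:20]:
            once = rf.canonicalize_rule(rule)
            assert (once.rule_smarts, once.rule_smiles) == (rule.rule_smarts, rule.rule_smiles)
            twice = rf.canonicalize_rule(once)
            assert (twice.rule_smarts, twice.rule_smiles) == (once.rule_smarts, once.rule_smiles)

    def test_racemization_rule_degenerate_without_stereo(self, corpus, cofactors,
                                                         stereo_policy):
        rxn = corpus.reaction(corpus.racemization_id)
        center = rf.augment_stereo(rxn, rf.identify_reaction_center(rxn))
        comps = rf.decompose(rxn, center, cofactors, stereo_policy)
        for comp in comps:
            assert rf.extract_rule(comp, 4, False) is None       # degenerate
            assert rf.extract_rule(comp, 4, True) is not None    # parity flip

    def test_rule_keys_unique(self, nonstereo_result, stereo_result):
        for result in (nonstereo_result, stereo_result):
            keys = [r.key for r in result.rules]
            assert len(keys) == len(set(keys))

    def test_distinct_counts_monotone(self, nonstereo_result, stereo_result):
        for result in (nonstereo_result, stereo_result):
            counts = rf.count_distinct(result.rules)
            finite = [counts[(d, result.policy.stereo_enabled)]
                      for d in ALL_DIAMETERS if d is not None]
            assert finite == sorted(finite)


class TestApply:
    def test_round_trip_spot_checks(self, corpus, nonstereo_result):
        comp_by = component_index(nonstereo_result)
        rules = hpp_forward_rules(nonstereo_result, corpus)
        comp = comp_by[("TRANS1", rules[0].substrate_id)]
        expected = component_products(comp, stereo=False)
        for d in (0, 4, None):
            out = rf.apply_rule(rules[d], comp.substrate)
            assert expected in out
        assert rf.apply_rule(rules[None], comp.substrate) == frozenset([expected])

    def test_no_match_returns_empty_set(self, corpus, nonstereo_result):
        rules = hpp_forward_rules(nonstereo_result, corpus)
        assert rf.apply_rule(rules[4], "C") == frozenset()

    def test_promiscuity_monotone_over_diameters(self, corpus, nonstereo_result):
        """If a rule at diameter d matches a substrate, so do all smaller d."""
        rules = hpp_forward_rules(nonstereo_result, corpus)
        panel = list(corpus.analog_substrates.values()) + ["C", "CC(=O)C(=O)O"]
        for substrate in panel:
            matched = [d for d in ALL_DIAMETERS
                       if rf.apply_rule(rules[d], rf.MappedMolecule.from_smiles(substrate))]
            finite = [d for d in matched if d is not None]
            if finite:
                smallest = [d for d in ALL_DIAMETERS if d is not None and d <= max(finite)]
                assert finite == smallest

    def test_low_diameter_rule_transforms_analog(self, corpus, nonstereo_result):
        """Promiscuity: the truncated rule aminates a ring-substituted analog.

        The expected amino product is built by an independent manual rewrite
        of the analog (keto group -> amine on the same carbon).
        """
        rules = hpp_forward_rules(nonstereo_result, corpus)
        for analog in corpus.analog_substrates.values():
            assert "[C:7](=[O:8])" in analog
            amino = analog.replace("[C:7](=[O:8])", "[CH:7]([NH2:99])")
            expected_amino = rf.MappedMolecule.from_smiles(amino).canonical_smiles()
            out = rf.apply_rule(rules[2], rf.MappedMolecule.from_smiles(analog))
            expected = tuple(sorted([expected_amino, "O=C(O)CCC(=O)C(=O)O"]))
            assert expected in out

    def test_stereo_rule_requires_compatible_substrate(self, stereo_result):
        racem = [r for r in stereo_result.rules
                 if r.reaction_id == "RACEM1" and r.diameter == 4][0]
        assert rf.apply_rule(racem, "N[C@@H](C)C(=O)O")  # L-alanine: fires
        assert not rf.apply_rule(racem, "N[C@H](C)C(=O)O")  # D-alanine: no
        assert not rf.apply_rule(racem, "NC(C)C(=O)O")      # undefined: no

    def test_cis_trans_rule_flips_geometry(self, stereo_result):
        cis = [r for r in stereo_result.rules
               if r.reaction_id == "CIS1" and r.diameter == 4][0]
        out = rf.apply_rule(cis, "OC(=O)/C=C\\C(=O)O")
        assert ("O=C(O)/C=C/C(=O)O",) in out
        assert not rf.apply_rule(cis, "OC(=O)/C=C/C(=O)O")

    def test_smarts_parse_as_reactions(self, nonstereo_result, stereo_result):
        from rdkit.Chem import AllChem
        for result in (nonstereo_result, stereo_result):
            for rule in result.rules:
                rxn = AllChem.ReactionFromSmarts(rule.rule_smarts)
                assert rxn is not None
                assert rxn.GetNumReactantTemplates() == 1
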