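"""Shared fixtures: the deterministic corpus and full pipeline runs.

Pipeline results are session-scoped; every test reads, none mutates.
"""

from __future__ import annotations

import networkx as nx
import pytest

import ruleforge as rf

#: every diameter exercised by the suite, including 0 and the untruncated rule
ALL_DIAMETERS = (0, 2, 4, 6, 8, 10, 12, 14, 16, None)


@pytest.fixture(scope="session")
def corpus() -> rf.FixtureCorpus:
    return rf.generate_corpus(seed=42, n_variants=3)


@pytest.fixture(scope="session")
def cofactors() -> rf.CofactorList:
    return rf.CofactorList.default()


@pytest.fixture(scope="session")
def strict_policy() -> rf.RunPolicy:
    return rf.RunPolicy(mode="strict", stereo_enabled=False, diameters=ALL_DIAMETERS)


@pytest.fixture(scope="session")
def stereo_policy() -> rf.RunPolicy:
    return rf.RunPolicy(mode="strict", stereo_enabled=True, diameters=ALL_DIAMETERS)


@pytest.fixture(scope="session")
def diy_policy() -> rf.RunPolicy:
    return rf.RunPolicy(mode="diy", stereo_enabled=False, diameters=ALL_DIAMETERS)


@pytest.fixture(scope="session")
def nonstereo_result(corpus, strict_policy, cofactors) -> rf.PipelineResult:
    return rf.run_pipeline(corpus.reactions, strict_policy, cofactors)


@pytest.fixture(scope="session")
def stereo_result(corpus, stereo_policy, cofactors) -> rf.PipelineResult:
    return rf.run_pipeline(corpus.reactions, stereo_policy, cofactors)


@pytest.fixture(scope="session")
def diy_result(corpus, diy_policy) -> rf.PipelineResult:
    return rf.run_pipeline(corpus.reactions, diy_policy)


def component_products(component: rf.MonoComponent, *, stereo: bool) -> tuple[str, ...]:
    """Recorded product multiset of a component as canonical SMILES."""
    out = []
    for mol, count in component.products:
        out.extend([mol.canonical_smiles(keep_stereo=stereo)] * count)
    return tuple(sorted(out))


def component_index(result: rf.PipelineResult) -> dict[tuple, rf.MonoComponent]:
    return {(c.rule_reaction_id, c.substrate_id): c for c in result.components}


def brute_force_center(rxn: rf.MappedReaction) -> frozenset[int]:
    """Independent reacting-atom oracle via networkx environment tables.

    Builds one labelled graph per side over map numbers and diffs, per map,
    the node label (element, charge) together with the multiset of incident
    edge labels; one-sided maps are reacting by definition.
    """
    def side_graph(side) -> nx.Graph:
        g = nx.Graph()
        for si, sp in enumerate(side):
            mol = sp.molecule.mol

            def node(atom):
                m = atom.GetAtomMapNum()
                return m if m else (si, atom.GetIdx())

            for atom in mol.GetAtoms():
                g.add_node(node(atom), label=(atom.GetSymbol(), atom.GetFormalCharge()))
            for bond in mol.GetBonds():
                order = "ar" if bond.GetIsAromatic() else bond.GetBondTypeAsDouble()
                g.add_edge(node(bond.GetBeginAtom()), node(bond.GetEndAtom()),
                           label=order)
        return g

    left = side_graph(rxn.substrates)
    right = side_graph(rxn.products)
    mapped_left = {n for n in left.nodes if isinstance(n, int)}
    mapped_right = {n for n in right.nodes if isinstance(n, int)}
    reacting = set(mapped_left ^ mapped_right)
    for m in mapped_left & mapped_right:
        def env(g, node):
            edges = sorted(
                (str(nb) if isinstance(nb, int) else "u", str(g.edges[node, nb]["label"]))
                for nb in g.neighbors(node))
            return (g.nodes[node]["label"], tuple(edges))
        if env(left, m) != env(right, m):
            reacting.add(m)
    return frozenset(reacting)
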