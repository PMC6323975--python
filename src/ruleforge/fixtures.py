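"""Deterministic toy corpus of pre-mapped reactions.

The corpus emulates, at desk scale, the reaction classes a rule-extraction
run over curated metabolic databases must handle: an aminotransferase pair
(the keto/amino swap of tyrosine aminotransferase, EC 2.6.1.5), an amino
acid racemisation and a cis-trans isomerisation (rules only expressible
with stereochemistry), a lactone hydrolysis consuming water (cofactor
handling), an esterification (two-substrate decomposition), and three
rejection cases: passive transport (no change), an R-group reaction
(underspecified) and an unbalanced reaction (accepted only in DIY mode).
Ring-substituted analogs of the transamination substrate probe rule
promiscuity: the substituent sits 4-5 bonds from the reaction center, so
small-diameter rules must accept the analogs and large-diameter rules must
not.

Every entry carries hand-derived expected behaviour (verdict, reacting-atom
count, component count) used as the ground truth of the test suite.
"""

from __future__ import annotations

import dataclasses
import random
from pathlib import Path
from typing import Optional, Union

from .errors import RuleForgeError
from .reaction_io import MappedReaction, parse_mapped_reaction, write_reactions_tsv

# -- transamination: 4-hydroxyphenylpyruvate + L-glutamate ->
#    L-tyrosine + 2-oxoglutarate (keto C7=O8 and amino C15-N14 swap)
_HPP = "[OH:1][c:2]1[cH:3][cH:4][c:5]([CH2:6][C:7](=[O:8])[C:9](=[O:10])[OH:11])[cH:12][cH:13]1"
_LGLU = "[NH2:14][C@@H:15]([CH2:16][CH2:17][C:18](=[O:19])[OH:20])[C:21](=[O:22])[OH:23]"
_LTYR = "[OH:1][c:2]1[cH:3][cH:4][c:5]([CH2:6][C@H:7]([NH2:14])[C:9](=[O:10])[OH:11])[cH:12][cH:13]1"
_OXO = "[O:8]=[C:15]([CH2:16][CH2:17][C:18](=[O:19])[OH:20])[C:21](=[O:22])[OH:23]"

#: ring substituents for promiscuity analogs (mapped form)
_SUBSTITUENT_POOL: tuple[str, ...] = (
    "[F:24]", "[Cl:24]", "[Br:24]", "[CH3:24]", "[I:24]",
)


@dataclasses.dataclass(frozen=True)
class ExpectedBehavior:
    """Hand-derived ground truth for one corpus entry."""

    verdict_nonstereo: str
    verdict_stereo: str
    center_size_nonstereo: Optional[int] = None
    center_size_stereo: Optional[int] = None
    n_components: Optional[int] = None
    stereo_only: bool = False
    verdict_diy: Optional[str] = None        # differs from strict verdict
    center_size_diy: Optional[int] = None
    n_components_diy: Optional[int] = None


@dataclasses.dataclass(frozen=True)
class FixtureCorpus:
    """A generated corpus with its expectation table."""

    seed: int
    n_variants: int
    reactions: tuple[MappedReaction, ...]
    expected: dict[str, ExpectedBehavior]
    #: variant id -> unmapped analog of 4-hydroxyphenylpyruvate
    analog_substrates: dict[str, str]
    parent_transamination_id: str = "TRANS1"
    racemization_id: str = "RACEM1"
    cis_trans_id: str = "CIS1"
    hydrolysis_id: str = "HYDRO1"
    condensation_id: str = "ESTER1"

    def reaction(self, reaction_id: str) -> MappedReaction:
        for rxn in self.reactions:
            if rxn.reaction_id == reaction_id:
                return rxn
        raise KeyError(reaction_id)

    def write_tsv(self, path: Union[str, Path]) -> None:
        write_reactions_tsv(self.reactions, path)


def generate_corpus(seed: int = 42, n_variants: int = 3) -> FixtureCorpus:
    """Build the deterministic fixture corpus.

    ``n_variants`` substituted transamination analogs (max 5) are drawn
    without replacement from a fixed substituent pool with ``random.Random(seed)``;
    the same seed always yields a byte-identical corpus.
    """
    if n_variants < 1:
        raise RuleForgeError("n_variants must be >= 1")
    if n_variants > len(_SUBSTITUENT_POOL):
        raise RuleForgeError(f"at most {len(_SUBSTITUENT_POOL)} variants supported")
    rng = random.Random(seed)
    chosen = rng.sample(_SUBSTITUENT_POOL, n_variants)

    reactions: list[MappedReaction] = []
    expected: dict[str, ExpectedBehavior] = {}
    analogs: dict[str, str] = {}

    def add(rid, text, ec=(), seqs=(), exp=None):
        reactions.append(parse_mapped_reaction(text, rid, ec, seqs))
        expected[rid] = exp

    # 1. transamination (EC 2.6.1.5 worked example): 10 annotated sequences
    add("TRANS1", f"{_HPP}.{_LGLU}>>{_LTYR}.{_OXO}",
        ec=("2.6.1.5",), seqs=tuple(f"T{i:02d}" for i in range(1, 11)),
        exp=ExpectedBehavior("ok", "ok", 4, 4, n_components=4))

    # 1b. promiscuity analogs, with pairwise-overlapping sequence sets
    for k, sub_mapped in enumerate(chosen, start=1):
        rid = f"TRANS1_VAR{k}"
        hpp = _HPP.replace("[cH:3]", f"[c:3]({sub_mapped})")
        tyr = _LTYR.replace("[cH:3]", f"[c:3]({sub_mapped})")
        add(rid, f"{hpp}.{_LGLU}>>{tyr}.{_OXO}",
            ec=("2.6.1.5",), seqs=(f"V{k:02d}", f"V{k + 1:02d}"),
            exp=ExpectedBehavior("ok", "ok", 4, 4, n_components=4))
        # analog substrate = parent skeleton substituted at the map-3 ring
        # position (4-5 bonds from the reacting keto group); map numbers are
        # stripped by rule application
        analogs[rid] = hpp

    # 2. racemisation (EC 5.1 class): rule exists only with stereo on
    add("RACEM1",
        "[NH2:1][C@@H:2]([CH3:3])[C:4](=[O:5])[OH:6]"
        ">>[NH2:1][C@H:2]([CH3:3])[C:4](=[O:5])[OH:6]",
        ec=("5.1.1.1",), seqs=("R01", "R02"),
        exp=ExpectedBehavior("no-change", "ok", None, 1, n_components=2,
                             stereo_only=True))

    # 3. cis-trans isomerisation (EC 5.2 class): maleate -> fumarate
    add("CIS1",
        r"[OH:1][C:2](=[O:3])/[CH:4]=[CH:5]\[C:6](=[O:7])[OH:8]"
        r">>[OH:1][C:2](=[O:3])/[CH:4]=[CH:5]/[C:6](=[O:7])[OH:8]",
        ec=("5.2.1.1",), seqs=("C01", "C02", "C03"),
        exp=ExpectedBehavior("no-change", "ok", None, 2, n_components=2,
                             stereo_only=True))

    # 4. lactone hydrolysis with water as cofactor (EC 3.1 class)
    add("HYDRO1",
        "[CH2:1]1[CH2:2][CH2:3][C:4](=[O:5])[O:6]1.[OH2:7]"
        ">>[OH:6][CH2:1][CH2:2][CH2:3][C:4](=[O:5])[OH:7]",
        ec=("3.1.1.25",), seqs=("H01",),
        exp=ExpectedBehavior("ok", "ok", 3, 3, n_components=2))

    # 5. two-substrate condensation releasing water
    add("ESTER1",
        "[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][CH2:6][OH:7]"
        ">>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5].[OH2:4]",
        ec=("3.1.1.1",), seqs=("E01", "E02", "E03"),
        exp=ExpectedBehavior("ok", "ok", 3, 3, n_components=3))

    # 6. passive transport: both sides identical
    add("TRANSPORT1", "[OH2:1]>>[OH2:1]",
        exp=ExpectedBehavior("no-change", "no-change"))

    # 7. R-group reaction: wildcard atom, not fully characterised
    add("RGROUP1", "[*:1][CH2:2][OH:3]>>[*:1][CH:2]=[O:3]",
        exp=ExpectedBehavior("underspecified", "underspecified"))

    # 8. unbalanced decarboxylation (CO2 omitted): rejected in strict mode,
    #    accepted on-the-fly where the leaving atoms count as reacting
    add("UNBAL1",
        "[CH3:1][C:2](=[O:3])[C:4](=[O:5])[OH:6]>>[CH3:1][CH:2]=[O:3]",
        exp=ExpectedBehavior("unbalanced", "unbalanced",
                             verdict_diy="ok", center_size_diy=4,
                             n_components_diy=2))

    return FixtureCorpus(
        seed=seed, n_variants=n_variants,
        reactions=tuple(reactions), expected=expected,
        analog_substrates=analogs)
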