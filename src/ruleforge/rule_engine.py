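"""Mono-substrate decomposition, diameter-truncated rule extraction,
canonicalisation, and single-step rule application.

A *rule* is the transformation between one substrate and the products that
inherit at least one of its mapped atoms, truncated to the atoms lying
within ``diameter/2`` bonds of a reacting atom.  Rules are emitted both as
reaction SMARTS (the executable transformation pattern) and as a fragment
reaction SMILES (a human-readable depiction used for deduplication).

Truncation semantics
--------------------
* Substrate side: exactly the atoms at graph distance <= diameter/2 from a
  reacting atom are retained; bonds crossing the boundary are cut.
* Product side: atoms mapped to retained substrate atoms are retained, plus
  *incoming* atoms (unmapped or mapped to a co-substrate) in full, so that
  applying the rule to its source substrate regenerates the recorded
  products; atoms mapped to truncated substrate atoms are carried through
  by the matcher at application time and must not be duplicated in the
  pattern.
* Stereo mode additionally retains the direct neighbours of every atom
  whose R/S or E/Z descriptor changes: a stereo descriptor is only defined
  relative to those neighbours.

Atom-query content: element, aromaticity and formal charge are always
asserted; total-H counts only on reacting atoms (H-count changes encode the
transformation); degree and ring membership only on interior atoms (those
whose full heavy-atom neighbourhood is retained) so that truncated rules
generalise at the boundary while full-diameter rules stay exact.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional, Union

from rdkit import Chem
from rdkit.Chem import AllChem

from . import _chem
from .errors import DiameterError, NoPrimarySubstrateError
from .reaction_center import ReactionCenter
from .reaction_io import (CofactorList, Diameter, MappedMolecule,
                          MappedReaction, RunPolicy)

logger = logging.getLogger(__name__)

_REVERSE_SUFFIX = "_rev"


@dataclasses.dataclass(frozen=True)
class MonoComponent:
    """One direction-specific single-substrate sub-reaction."""

    parent_reaction_id: str
    direction: str  # 'forward' | 'reverse'
    substrate: MappedMolecule
    products: tuple[tuple[MappedMolecule, int], ...]
    removed_cofactors: tuple[str, ...]
    center: ReactionCenter

    @property
    def rule_reaction_id(self) -> str:
        if self.direction == "reverse":
            return self.parent_reaction_id + _REVERSE_SUFFIX
        return self.parent_reaction_id

    @property
    def substrate_id(self) -> str:
        return self.substrate.canonical_smiles()


@dataclasses.dataclass(frozen=True)
class ReactionRule:
    """A (reaction, substrate, diameter, isStereo) keyed transformation."""

    reaction_id: str
    parent_reaction_id: str
    substrate_id: str
    diameter: Diameter             # None means "max" (no truncation)
    is_stereo: bool
    direction: str
    rule_smarts: str
    rule_smiles: str
    products: tuple[tuple[str, int], ...]   # (product pattern SMILES, stoichiometry)
    score: Optional[float] = None
    n_sequences: Optional[int] = None
    score_provenance: Optional[str] = None
    #: pattern fragment molecules (substrate, (products...)); not part of
    #: rule identity, retained so canonicalisation can be re-derived
    _frags: Optional[tuple] = dataclasses.field(
        default=None, compare=False, repr=False)

    @property
    def key(self) -> tuple:
        return (self.reaction_id, self.substrate_id, self.diameter, self.is_stereo)

    @property
    def canonical_key(self) -> tuple:
        """Identity used for distinct-rule counting and score grouping."""
        return (self.rule_smarts, self.diameter, self.is_stereo)

    def with_score(self, score: float, n_sequences: int, provenance: str) -> "ReactionRule":
        return dataclasses.replace(
            self, score=score, n_sequences=n_sequences, score_provenance=provenance)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def decompose(rxn: MappedReaction, center: ReactionCenter,
              cofactors: CofactorList, policy: RunPolicy) -> list[MonoComponent]:
    """Split a reaction into direction-specific mono-substrate components.

    One component is produced per non-cofactor substrate in the forward
    direction and per non-cofactor product in the reverse direction (rules
    are generated for both directions, doubling the rule count).  Each
    component keeps only the products sharing >= 1 mapped atom with its
    substrate; cofactor species never seed a component and are dropped from
    product lists while cofactor removal is on.
    """
    components: list[MonoComponent] = []
    for direction, view in (("forward", rxn), ("reverse", rxn.reverse())):
        primaries = [sp for sp in view.substrates
                     if not (policy.cofactor_removal and sp.molecule in cofactors)]
        if not primaries:
            raise NoPrimarySubstrateError(
                f"reaction {rxn.reaction_id!r}: no primary substrate in the "
                f"{direction} direction (all substrates are cofactors)")
        for sub_sp in primaries:
            sub_maps = sub_sp.molecule.map_numbers
            kept: list[tuple[MappedMolecule, int]] = []
            removed: list[str] = []
            for prod_sp in view.products:
                if policy.cofactor_removal and prod_sp.molecule in cofactors:
                    removed.append(prod_sp.molecule.canonical_smiles())
                    continue
                if sub_maps & prod_sp.molecule.map_numbers:
                    kept.append((prod_sp.molecule, prod_sp.count))
            components.append(MonoComponent(
                parent_reaction_id=rxn.reaction_id,
                direction=direction,
                substrate=sub_sp.molecule,
                products=tuple(kept),
                removed_cofactors=tuple(sorted(removed)),
                center=center,
            ))
    return components


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _truncate(mol: Chem.RWMol, retained: set[int]) -> Chem.RWMol:
    """Copy ``mol`` keeping only ``retained`` atom indices.

    Per-atom facts needed for query generation (original H count, degree,
    aromaticity, ring membership, interior flag) are recorded as atom
    properties before deletion.  Stereo descriptors that lose a defining
    neighbour are cleared: chiral tags on atoms with a removed heavy
    neighbour, and double-bond stereo whose stereo atoms are not all
    retained (together with the directional bonds expressing it).
    """
    work = Chem.RWMol(mol)
    for atom in work.GetAtoms():
        atom.SetIntProp("_origMap", atom.GetAtomMapNum())
        atom.SetIntProp("_origHs", atom.GetTotalNumHs())
        atom.SetIntProp("_origDeg", atom.GetDegree())
        atom.SetIntProp("_origArom", int(atom.GetIsAromatic()))
        atom.SetIntProp("_origRing", int(atom.IsInRing()))
        atom.SetIntProp(
            "_interior",
            int(all(nb.GetIdx() in retained for nb in atom.GetNeighbors())))

    for atom in work.GetAtoms():
        if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            if any(nb.GetIdx() not in retained for nb in atom.GetNeighbors()):
                atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    kept_stereo_bond_atoms: set[int] = set()
    for bond in work.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREONONE:
            continue
        stereo_atoms = set(bond.GetStereoAtoms())
        ends = {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
        if stereo_atoms <= retained and ends <= retained:
            kept_stereo_bond_atoms |= ends
        else:
            bond.SetStereo(Chem.BondStereo.STEREONONE)
    for bond in work.GetBonds():
        if bond.GetBondDir() in (Chem.BondDir.ENDUPRIGHT, Chem.BondDir.ENDDOWNRIGHT):
            if not ({bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
                    & kept_stereo_bond_atoms):
                bond.SetBondDir(Chem.BondDir.NONE)

    for idx in sorted(set(range(mol.GetNumAtoms())) - retained, reverse=True):
        work.RemoveAtom(idx)
    return work


def _canonical_renumber(frag: Chem.Mol) -> Chem.Mol:
    """Renumber fragment atoms into canonical order (map numbers ignored)."""
    probe = Chem.RWMol(frag)
    for atom in probe.GetAtoms():
        atom.SetAtomMapNum(0)
    probe.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(probe)
    ranks = list(Chem.CanonicalRankAtoms(probe, breakTies=True, includeChirality=True))
    order = sorted(range(frag.GetNumAtoms()), key=lambda i: ranks[i])
    out = Chem.RenumberAtoms(frag, order)
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def _atom_query(atom: Chem.Atom, *, substrate_side: bool) -> str:
    parts = [f"#{atom.GetAtomicNum()}",
             "a" if atom.GetIntProp("_origArom") else "A",
             f"{atom.GetFormalCharge():+d}"]
    if atom.GetIntProp("_react"):
        parts.append(f"H{atom.GetIntProp('_origHs')}")
    if substrate_side and atom.GetIntProp("_interior"):
        parts.append(f"D{atom.GetIntProp('_origDeg')}")
        parts.append("R" if atom.GetIntProp("_origRing") else "!R")
    return "[" + "&".join(parts) + f":{atom.GetAtomMapNum()}]"


def _fragment_smarts(frag: Chem.Mol, *, substrate_side: bool) -> str:
    work = Chem.RWMol(frag)
    for idx in range(work.GetNumAtoms()):
        old = work.GetAtomWithIdx(idx)
        qa = Chem.AtomFromSmarts(_atom_query(old, substrate_side=substrate_side))
        qa.SetChiralTag(old.GetChiralTag())
        qa.SetAtomMapNum(old.GetAtomMapNum())
        work.ReplaceAtom(idx, qa, preserveProps=False)
    return Chem.MolToSmarts(work)


def _assemble(sub_frag: Chem.Mol, prod_frags: list[Chem.Mol]):
    """Build (rule_smarts, rule_smiles, products) from final fragments."""
    sub_smiles = _chem.fragment_smiles(sub_frag)
    sub_smarts = _fragment_smarts(sub_frag, substrate_side=True)
    prod_entries = [(_chem.fragment_smiles(f), _fragment_smarts(f, substrate_side=False))
                    for f in prod_frags]
    prod_smiles_side = ".".join(smi for smi, _ in prod_entries)
    rule_smarts = f"({sub_smarts})>>({'.'.join(sma for _, sma in prod_entries)})"
    rule_smiles = f"{sub_smiles}>>{prod_smiles_side}"

    counts: dict[str, int] = {}
    for smi, _ in prod_entries:
        counts[smi] = counts.get(smi, 0) + 1
    seen: set[str] = set()
    products: list[tuple[str, int]] = []
    for smi, _ in prod_entries:
        if smi not in seen:
            seen.add(smi)
            products.append((smi, counts[smi]))
    return rule_smarts, rule_smiles, tuple(products), sub_smiles, prod_smiles_side


def extract_rule(component: MonoComponent, diameter: Diameter,
                 stereo: bool) -> Optional[ReactionRule]:
    """Extract the rule of ``component`` at one diameter.

    Returns ``None`` for degenerate rules (identical sides after
    canonicalisation, e.g. a racemisation processed without stereo) and for
    components whose substrate carries no reacting atom.
    """
    if diameter is not None and (not isinstance(diameter, int)
                                 or diameter < 0 or diameter % 2):
        raise DiameterError(f"diameter must be an even integer >= 0 or None, got {diameter!r}")
    radius = None if diameter is None else diameter // 2

    center = component.center
    reacting = center.reacting_maps
    stereo_changed = center.stereo_changed_maps if stereo else frozenset()

    sub_mol = Chem.RWMol(component.substrate.mol)
    prods = [Chem.RWMol(mol.mol) for mol, count in component.products for _ in range(count)]
    if not stereo:
        Chem.RemoveStereochemistry(sub_mol)
        for p in prods:
            Chem.RemoveStereochemistry(p)
    # atoms that react: changed environment, or unmapped (fate unknowable)
    for m in [sub_mol] + prods:
        for atom in m.GetAtoms():
            mapno = atom.GetAtomMapNum()
            atom.SetIntProp("_react", int(mapno == 0 or mapno in reacting))

    sub_map_of = {a.GetIdx(): a.GetAtomMapNum() for a in sub_mol.GetAtoms()}
    sub_idx_of = {m: i for i, m in sub_map_of.items() if m}
    sub_all_maps = frozenset(m for m in sub_map_of.values() if m)

    seeds = [i for i, m in sub_map_of.items() if m == 0 or m in reacting]
    if not seeds:
        return None

    if radius is None:
        retained_sub = set(sub_map_of)
    else:
        dmat = Chem.GetDistanceMatrix(sub_mol)
        retained_sub = {i for i in sub_map_of
                        if min(dmat[i][s] for s in seeds) <= radius}
    # stereo-changing atoms keep their full neighbourhood (descriptor support)
    for i in list(retained_sub):
        if sub_map_of[i] in stereo_changed:
            retained_sub |= {nb.GetIdx() for nb in sub_mol.GetAtomWithIdx(i).GetNeighbors()}
    # ... including support demanded by the product side (e.g. a created
    # stereocentre whose neighbours lie outside the substrate sphere)
    if stereo_changed:
        for pmol in prods:
            for atom in pmol.GetAtoms():
                if atom.GetAtomMapNum() in stereo_changed:
                    for nb in atom.GetNeighbors():
                        m = nb.GetAtomMapNum()
                        if m in sub_all_maps:
                            retained_sub.add(sub_idx_of[m])

    retained_maps = frozenset(sub_map_of[i] for i in retained_sub if sub_map_of[i])

    sub_frag = _canonical_renumber(_truncate(sub_mol, retained_sub))

    # canonical map renumbering: substrate atoms first, in canonical order
    new_map: dict[int, int] = {}
    next_map = 1
    for atom in sub_frag.GetAtoms():
        orig = atom.GetIntProp("_origMap")
        atom.SetAtomMapNum(next_map)
        if orig:
            new_map[orig] = next_map
        next_map += 1

    prod_frags: list[Chem.Mol] = []
    for pmol in prods:
        keep = set()
        for atom in pmol.GetAtoms():
            m = atom.GetAtomMapNum()
            incoming = (m == 0) or (m not in sub_all_maps)
            if incoming or m in retained_maps:
                keep.add(atom.GetIdx())
        if not keep:
            logger.info("product dropped entirely by truncation in %s",
                        component.rule_reaction_id)
            continue
        prod_frags.append(_canonical_renumber(_truncate(pmol, keep)))

    if not prod_frags:
        return None

    # deterministic product order before assigning incoming maps
    def _sort_key(frag: Chem.Mol) -> str:
        shadow = Chem.RWMol(frag)
        for atom in shadow.GetAtoms():
            atom.SetAtomMapNum(new_map.get(atom.GetIntProp("_origMap"), 0))
        return _chem.fragment_smiles(shadow)

    prod_frags.sort(key=_sort_key)
    for frag in prod_frags:
        for atom in frag.GetAtoms():
            orig = atom.GetIntProp("_origMap")
            if orig in new_map:
                atom.SetAtomMapNum(new_map[orig])
            else:
                atom.SetAtomMapNum(next_map)
                next_map += 1

    rule_smarts, rule_smiles, products, sub_smiles, prod_side = _assemble(
        sub_frag, prod_frags)

    if sub_smiles == prod_side:
        logger.info("degenerate rule suppressed for %s at diameter %s",
                    component.rule_reaction_id, diameter)
        return None

    return ReactionRule(
        reaction_id=component.rule_reaction_id,
        parent_reaction_id=component.parent_reaction_id,
        substrate_id=component.substrate_id,
        diameter=diameter,
        is_stereo=stereo,
        direction=component.direction,
        rule_smarts=rule_smarts,
        rule_smiles=rule_smiles,
        products=products,
        _frags=(sub_frag, tuple(prod_frags)),
    )


def canonicalize_rule(rule: ReactionRule) -> ReactionRule:
    """Rewrite the rule strings in canonical atom order and map numbering.

    ``extract_rule`` emits canonical strings already, so this is idempotent:
    re-deriving the strings from the stored pattern fragments reproduces
    them byte-identically.  Rules loaded without fragments (e.g. from a
    database) are returned unchanged — their strings were canonical when
    stored.
    """
    if rule._frags is None:
        return rule
    sub_frag, prod_frags = rule._frags
    sub_frag = _canonical_renumber(sub_frag)
    prod_frags = [_canonical_renumber(f) for f in prod_frags]
    rule_smarts, rule_smiles, products, _, _ = _assemble(sub_frag, list(prod_frags))
    return dataclasses.replace(
        rule, rule_smarts=rule_smarts, rule_smiles=rule_smiles, products=products,
        _frags=(sub_frag, tuple(prod_frags)))


def count_distinct(rules: Iterable[ReactionRule]) -> dict[tuple, int]:
    """Distinct canonical rule count per (diameter, is_stereo)."""
    buckets: dict[tuple, set[str]] = {}
    for rule in rules:
        buckets.setdefault((rule.diameter, rule.is_stereo), set()).add(rule.rule_smarts)
    return {k: len(v) for k, v in sorted(
        buckets.items(), key=lambda kv: (kv[0][0] is None, kv[0][0] or 0, kv[0][1]))}


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def _as_plain_mol(substrate: Union[str, Chem.Mol, MappedMolecule]) -> Chem.Mol:
    if isinstance(substrate, MappedMolecule):
        mol = Chem.RWMol(substrate.mol)
    elif isinstance(substrate, Chem.Mol):
        mol = Chem.RWMol(substrate)
    else:
        parsed = Chem.MolFromSmiles(str(substrate))
        if parsed is None:
            raise ValueError(f"unparseable substrate {substrate!r}")
        mol = Chem.RWMol(parsed)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol.GetMol()


def apply_rule(rule: ReactionRule,
               substrate: Union[str, Chem.Mol, MappedMolecule],
               ) -> frozenset[tuple[str, ...]]:
    """Apply ``rule`` to an unmapped substrate.

    Returns the set of distinct product multisets (each a sorted tuple of
    canonical product SMILES), one per successful template match; empty when
    the pattern does not match.  Matches whose rewrite is chemically invalid
    are discarded with a warning; stereo rules only fire on matches
    compatible with the substrate's stereo descriptors (RDKit's reaction
    runner does not itself filter matches by chirality, so matches are
    checked against chirality-aware substructure matches).
    """
    mol = _as_plain_mol(substrate)
    rxn = AllChem.ReactionFromSmarts(rule.rule_smarts)
    rxn.Initialize()

    chiral_matches: Optional[list[dict[int, int]]] = None
    if rule.is_stereo:
        template = rxn.GetReactantTemplate(0)
        chiral_matches = []
        for match in mol.GetSubstructMatches(template, uniquify=False,
                                             useChirality=True, maxMatches=4096):
            chiral_matches.append({
                atom.GetAtomMapNum(): match[atom.GetIdx()]
                for atom in template.GetAtoms() if atom.GetAtomMapNum()})

    results: set[tuple[str, ...]] = set()
    for prod_set in rxn.RunReactants((mol,)):
        merged = prod_set[0]  # grouped product template -> single molecule
        if chiral_matches is not None:
            used = {}
            for atom in merged.GetAtoms():
                if atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx"):
                    used[atom.GetIntProp("old_mapno")] = atom.GetIntProp("react_atom_idx")
            if not any(all(cm.get(m) == i for m, i in used.items())
                       for cm in chiral_matches):
                continue
        try:
            Chem.SanitizeMol(merged)
        except Exception as exc:
            logger.warning("invalid rewrite discarded for %s: %s", rule.reaction_id, exc)
            continue
        frag_smiles = []
        for frag in Chem.GetMolFrags(merged, asMols=True, sanitizeFrags=False):
            frag_smiles.append(_chem.canonical_smiles(frag, keep_maps=False))
        results.add(tuple(sorted(frag_smiles)))
    return frozenset(results)
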