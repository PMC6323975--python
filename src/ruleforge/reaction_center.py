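"""Reaction-center identification from the atom-atom mapping.

The reacting-atom set is the set of map numbers whose incident bond multiset
(neighbour map number + bond order), formal charge, or existence differs
between the two sides of a mapped reaction.  In stereo mode the set is
augmented with tetrahedral atoms whose R/S descriptor is created, inverted
or deleted across the reaction, and with both atoms of every double bond
whose E/Z descriptor changes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

from rdkit import Chem

from . import _chem
from .errors import StereoPerceptionError
from .reaction_io import MappedReaction

# environment of one mapped atom: (atomic number, formal charge,
#                                  sorted ((neighbour map, bond order), ...))
AtomEnv = tuple[int, int, tuple[tuple[int, str], ...]]


@dataclasses.dataclass(frozen=True)
class ReactionCenter:
    """The set of atom-map numbers that react (optionally stereo-augmented)."""

    reacting_maps: frozenset[int]
    stereo_added_maps: frozenset[int] = frozenset()
    #: atoms whose R/S or E/Z descriptor changes (used by the rule engine to
    #: keep their neighbourhood writable at small diameters)
    stereo_changed_maps: frozenset[int] = frozenset()
    is_stereo_augmented: bool = False

    def __bool__(self) -> bool:
        return bool(self.reacting_maps)

    def to_json(self, reaction_id: str, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps({reaction_id: sorted(self.reacting_maps)})
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _side_envs(rxn: MappedReaction, side: str) -> dict[int, AtomEnv]:
    envs: dict[int, AtomEnv] = {}
    species = rxn.substrates if side == "substrates" else rxn.products
    for sp in species:
        mol = sp.molecule.mol
        for atom in mol.GetAtoms():
            m = atom.GetAtomMapNum()
            if not m:
                continue
            bonds = sorted(
                (bond.GetOtherAtom(atom).GetAtomMapNum(), _chem.bond_order_token(bond))
                for bond in atom.GetBonds()
            )
            envs[m] = (atom.GetAtomicNum(), atom.GetFormalCharge(), tuple(bonds))
    return envs


def identify_reaction_center(rxn: MappedReaction) -> ReactionCenter:
    """Diff per-atom environments between the two sides of ``rxn``.

    Atoms present on one side only (appearing/disappearing species, e.g. in
    DIY unbalanced mode) are treated as reacting.  An empty center signals a
    no-change reaction and feeds back into validation; it is returned, not
    raised.
    """
    sub = _side_envs(rxn, "substrates")
    prod = _side_envs(rxn, "products")
    reacting: set[int] = set(sub.keys()) ^ set(prod.keys())
    for m in sub.keys() & prod.keys():
        if sub[m] != prod[m]:
            reacting.add(m)
    return ReactionCenter(reacting_maps=frozenset(reacting))


def _stereo_descriptors(rxn: MappedReaction, side: str):
    """Per-side CIP codes by map number and E/Z labels by map-number pair."""
    atom_desc: dict[int, str] = {}
    bond_desc: dict[frozenset[int], str] = {}
    species = rxn.substrates if side == "substrates" else rxn.products
    for sp in species:
        mol = Chem.RWMol(sp.molecule.mol)
        try:
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        except Exception as exc:  # pragma: no cover - defensive
            raise StereoPerceptionError(
                f"stereo perception failed on {sp.molecule.mapped_smiles!r}: {exc}") from exc
        for atom in mol.GetAtoms():
            m = atom.GetAtomMapNum()
            if not m:
                continue
            if atom.HasProp("_CIPCode"):
                atom_desc[m] = atom.GetProp("_CIPCode")
        for bond in mol.GetBonds():
            stereo = bond.GetStereo()
            if stereo in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
                label = "E"
            elif stereo in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
                label = "Z"
            else:
                continue
            m1 = bond.GetBeginAtom().GetAtomMapNum()
            m2 = bond.GetEndAtom().GetAtomMapNum()
            if m1 and m2:
                bond_desc[frozenset((m1, m2))] = label
    return atom_desc, bond_desc


def augment_stereo(rxn: MappedReaction, center: ReactionCenter) -> ReactionCenter:
    """Add atoms with changing R/S or E/Z descriptors to the reacting set.

    A descriptor that is defined on one side only counts as a creation or
    deletion of chirality; both atoms of a switching double bond are added
    (their stereo-determining substituents enter via the diameter sphere).
    """
    sub_atoms, sub_bonds = _stereo_descriptors(rxn, "substrates")
    prod_atoms, prod_bonds = _stereo_descriptors(rxn, "products")

    shared = rxn.side_maps("substrates") & rxn.side_maps("products")
    changed: set[int] = set()
    for m in shared:
        if sub_atoms.get(m) != prod_atoms.get(m):
            changed.add(m)
    for pair in set(sub_bonds) | set(prod_bonds):
        if pair <= shared and sub_bonds.get(pair) != prod_bonds.get(pair):
            changed |= pair

    return ReactionCenter(
        reacting_maps=center.reacting_maps | changed,
        stereo_added_maps=frozenset(changed - center.reacting_maps),
        stereo_changed_maps=frozenset(changed),
        is_stereo_augmented=True,
    )
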