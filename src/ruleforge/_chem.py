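"""Small RDKit helpers shared across modules."""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem  # noqa: F401  (re-exported for convenience)

# Reaction parsing/running is chatty on stderr (unmapped-atom notes etc.);
# those messages are informational for our use of mono-component templates.
RDLogger.DisableLog("rdApp.warning")


def mol_copy(mol: Chem.Mol) -> Chem.RWMol:
    return Chem.RWMol(mol)


def canonical_smiles(mol: Chem.Mol, *, keep_maps: bool = False,
                     keep_stereo: bool = True) -> str:
    """Canonical SMILES of ``mol``; atom maps and stereo stripped on request."""
    work = Chem.RWMol(mol)
    if not keep_maps:
        for atom in work.GetAtoms():
            atom.SetAtomMapNum(0)
    if not keep_stereo:
        Chem.RemoveStereochemistry(work)
    return Chem.MolToSmiles(work)


def fragment_smiles(frag: Chem.Mol) -> str:
    """Canonical SMILES of a possibly unsanitisable fragment.

    Truncated rule fragments may contain aromatic atoms whose ring was cut;
    they cannot be kekulised, so ring perception is refreshed without a full
    sanitisation round.
    """
    work = Chem.RWMol(frag)
    work.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(work)
    return Chem.MolToSmiles(work)


def element_counts(mol: Chem.Mol) -> dict[str, int]:
    """Element multiset including implicit/explicit hydrogens."""
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def total_charge(mol: Chem.Mol) -> int:
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


def map_numbers(mol: Chem.Mol) -> list[int]:
    """Non-zero atom-map numbers in atom-index order (may contain duplicates)."""
    return [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()]


def bond_order_token(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic() or bond.GetBondType() == Chem.BondType.AROMATIC:
        return "ar"
    return {
        Chem.BondType.SINGLE: "1",
        Chem.BondType.DOUBLE: "2",
        Chem.BondType.TRIPLE: "3",
    }.get(bond.GetBondType(), str(bond.GetBondType()))
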