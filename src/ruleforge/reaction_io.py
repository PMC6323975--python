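"""Parsing, normalisation and validation of atom-mapped reactions.

The unit of input is a fully atom-mapped reaction SMILES in the Daylight
``substrates>>products`` convention, where the atom-atom mapping (AAM) is
carried by bracket atom-map numbers shared between the two sides.  Mapping
is *required input*: inferring an AAM is a research problem of its own and
is deliberately out of scope here.

Reactions can also be read from a one-reaction-per-line TSV dialect::

    reaction_id<TAB>mapped-reaction-smiles<TAB>ec;ec<TAB>accession;accession

where the last two columns are optional.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path
from typing import NamedTuple, Optional, Union

import yaml
from rdkit import Chem

from . import _chem
from .errors import (CofactorFileError, MappingError, PolicyError,
                     ReactionParseError)

#: Diameter value meaning "no truncation" (the D = infinity rule).
MAX_DIAMETER = None

Diameter = Optional[int]


class MappedMolecule:
    """One chemical species with (possibly partial) atom-map numbers.

    Thin wrapper around an RDKit molecule guaranteeing that non-zero map
    numbers are unique within the molecule and exposing canonical structure
    strings.  The wrapped molecule must not be mutated by callers.
    """

    __slots__ = ("_mol",)

    def __init__(self, mol: Chem.Mol):
        maps = _chem.map_numbers(mol)
        if len(maps) != len(set(maps)):
            dup = sorted(m for m in set(maps) if maps.count(m) > 1)
            raise MappingError(f"duplicate atom-map number(s) {dup} within one molecule")
        self._mol = mol

    @classmethod
    def from_smiles(cls, text: str) -> "MappedMolecule":
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise ReactionParseError(f"unparseable species {text!r}")
        return cls(mol)

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def mapped_smiles(self) -> str:
        """Canonical SMILES retaining atom-map numbers (round-trip form)."""
        return Chem.MolToSmiles(self._mol)

    def canonical_smiles(self, *, keep_stereo: bool = True) -> str:
        """Canonical structure string with map numbers stripped."""
        return _chem.canonical_smiles(self._mol, keep_maps=False, keep_stereo=keep_stereo)

    @property
    def map_numbers(self) -> frozenset[int]:
        return frozenset(_chem.map_numbers(self._mol))

    @property
    def num_heavy_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    def has_wildcard(self) -> bool:
        """True when the species contains a dummy/R-group atom (``*``)."""
        return any(a.GetAtomicNum() == 0 for a in self._mol.GetAtoms())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MappedMolecule({self.mapped_smiles!r})"


class Species(NamedTuple):
    """A molecule together with its stoichiometric count on one side."""

    molecule: MappedMolecule
    count: int


@dataclasses.dataclass(frozen=True)
class MappedReaction:
    """A fully parsed atom-mapped multi-substrate reaction with annotations."""

    reaction_id: str
    substrates: tuple[Species, ...]
    products: tuple[Species, ...]
    ec_numbers: tuple[str, ...] = ()
    sequence_ids: tuple[str, ...] = ()
    direction_label: str = "forward"

    def __post_init__(self):
        for side_name, side in (("substrate", self.substrates), ("product", self.products)):
            seen: set[int] = set()
            for sp in side:
                maps = sp.molecule.map_numbers
                if sp.count > 1 and maps:
                    raise MappingError(
                        f"mapped species repeated {sp.count}x on the {side_name} side "
                        f"of {self.reaction_id!r}")
                clash = seen & maps
                if clash:
                    raise MappingError(
                        f"atom-map number(s) {sorted(clash)} duplicated on the "
                        f"{side_name} side of {self.reaction_id!r}")
                seen |= maps

    def side_maps(self, side: str) -> frozenset[int]:
        species = self.substrates if side == "substrates" else self.products
        out: set[int] = set()
        for sp in species:
            out |= sp.molecule.map_numbers
        return frozenset(out)

    def reverse(self) -> "MappedReaction":
        """Same chemistry read right-to-left."""
        return dataclasses.replace(
            self,
            substrates=self.products,
            products=self.substrates,
            direction_label="reverse" if self.direction_label == "forward" else "forward",
        )

    def to_string(self) -> str:
        """Canonical, deterministic mapped reaction string."""
        def side(species: tuple[Species, ...]) -> str:
            toks: list[str] = []
            for sp in species:
                toks.extend([sp.molecule.mapped_smiles] * sp.count)
            return ".".join(sorted(toks))

        return f"{side(self.substrates)}>>{side(self.products)}"


@dataclasses.dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of reaction validation; rejection is a verdict, not an error."""

    accepted: bool
    reason: str  # 'ok' | 'no-change' | 'unbalanced' | 'underspecified' | 'missing-structure'
    warnings: tuple[str, ...] = ()


@dataclasses.dataclass
class RunPolicy:
    """How a run treats balance, cofactors, stereo and diameters.

    ``diy`` mode is the on-the-fly variant: every structure is a primary
    compound (no cofactor removal) and unbalanced reactions are allowed.
    """

    mode: str = "strict"
    stereo_enabled: bool = False
    diameters: tuple[Diameter, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
    cofactor_removal: bool = True

    def __post_init__(self):
        if self.mode not in ("strict", "diy"):
            raise PolicyError(f"unknown mode {self.mode!r}")
        if self.mode == "diy":
            self.cofactor_removal = False
        norm: list[Diameter] = []
        for d in self.diameters:
            if isinstance(d, str):
                if d.lower() in ("max", "inf", "infinity"):
                    d = MAX_DIAMETER
                else:
                    d = int(d)
            if d is not MAX_DIAMETER:
                if d < 0 or d % 2:
                    raise PolicyError(f"diameter must be an even integer >= 0, got {d}")
            norm.append(d)
        finite = sorted({d for d in norm if d is not MAX_DIAMETER})
        self.diameters = tuple(finite) + ((MAX_DIAMETER,) if MAX_DIAMETER in norm else ())

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunPolicy":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


#: Stand-in default cofactor list (water, gases, phosphates, nucleotide
#: cofactors, ammonia and common ions).  User lists override it entirely.
DEFAULT_COFACTOR_SMILES: tuple[str, ...] = (
    "O",                # water
    "O=C=O",            # CO2
    "O=O",              # O2
    "OO",               # H2O2
    "N",                # ammonia
    "OP(=O)(O)O",       # phosphate
    "OP(=O)(O)OP(=O)(O)O",  # diphosphate
    "[Na+]", "[K+]", "[Cl-]", "[Ca+2]", "[Mg+2]", "[Fe+2]", "[Fe+3]", "[Zn+2]",
    # adenosine phosphates
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)O)C(O)C1O",                          # AMP
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O",                 # ADP
    "Nc1ncnc2c1ncn2C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O",        # ATP
    # nicotinamide cofactors (NAD+/NADH, NADP+/NADPH; non-stereo skeletons)
    "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)c1",
    "NC(=O)C1=CN(C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(O)C3O)C(O)C2O)C=CC1",
    "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)C(O)C2O)c1",
    "NC(=O)C1=CN(C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)C(OP(=O)(O)O)C3O)C=CC1)C(O)C2O",
)


class CofactorList:
    """Cofactor membership by canonical structure-string equality.

    Matching ignores atom-map numbers (entries and queries are canonicalised
    with maps stripped); names play no role.
    """

    def __init__(self, entries: Iterable[str] = ()):
        self._entries: frozenset[str] = frozenset(entries)

    @classmethod
    def from_smiles(cls, smiles: Iterable[str]) -> "CofactorList":
        canon = set()
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise CofactorFileError(f"unparseable cofactor structure {smi!r}")
            canon.add(_chem.canonical_smiles(mol, keep_maps=False))
        return cls(canon)

    @classmethod
    def default(cls) -> "CofactorList":
        return cls.from_smiles(DEFAULT_COFACTOR_SMILES)

    @property
    def entries(self) -> frozenset[str]:
        return self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, molecule) -> bool:
        if isinstance(molecule, MappedMolecule):
            key = molecule.canonical_smiles()
        elif isinstance(molecule, Chem.Mol):
            key = _chem.canonical_smiles(molecule, keep_maps=False)
        else:
            mol = Chem.MolFromSmiles(str(molecule))
            if mol is None:
                return False
            key = _chem.canonical_smiles(mol, keep_maps=False)
        return key in self._entries


def load_cofactors(path: Union[str, Path]) -> CofactorList:
    """Read a cofactor SMILES list (one per line, ``#`` comments allowed)."""
    canon: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        mol = Chem.MolFromSmiles(line)
        if mol is None:
            raise CofactorFileError(f"{path}:{lineno}: unparseable structure {line!r}")
        canon.add(_chem.canonical_smiles(mol, keep_maps=False))
    return CofactorList(canon)


def _parse_side(side_text: str, side_name: str) -> tuple[Species, ...]:
    counts: dict[str, int] = {}
    order: list[str] = []
    for token in side_text.split("."):
        token = token.strip()
        if not token:
            raise ReactionParseError(f"empty species token on the {side_name} side")
        mol = Chem.MolFromSmiles(token)
        if mol is None:
            raise ReactionParseError(f"unparseable species {token!r} on the {side_name} side")
        key = Chem.MolToSmiles(mol)
        if key not in counts:
            counts[key] = 0
            order.append(key)
        counts[key] += 1
    return tuple(Species(MappedMolecule.from_smiles(k), counts[k]) for k in order)


def parse_mapped_reaction(text: str, reaction_id: str,
                          ec_numbers: Sequence[str] = (),
                          sequence_ids: Sequence[str] = ()) -> MappedReaction:
    """Parse a ``substrates>>products`` mapped reaction string.

    Repeated identical species are aggregated into stoichiometry counts;
    the per-side map-number uniqueness invariant is enforced.
    """
    parts = text.split(">>")
    if len(parts) != 2:
        raise ReactionParseError(
            f"reaction {reaction_id!r}: expected exactly one '>>' separator in {text!r}")
    left, right = parts
    if not left.strip() or not right.strip():
        raise ReactionParseError(f"reaction {reaction_id!r}: empty reaction side")
    return MappedReaction(
        reaction_id=reaction_id,
        substrates=_parse_side(left, "substrate"),
        products=_parse_side(right, "product"),
        ec_numbers=tuple(ec_numbers),
        sequence_ids=tuple(sequence_ids),
    )


def validate_reaction(rxn: MappedReaction, policy: RunPolicy) -> ValidationVerdict:
    """Apply the input filters: R-groups, balance (strict only), no-change.

    The checks mirror the ingestion filters of rule databases built from
    curated metabolic reactions: species with wildcard atoms are not fully
    characterised, unbalanced reactions indicate missing participants, and
    reactions whose two sides are the same multiset of structures (e.g.
    passive transport) carry no transformation to learn.  In ``diy`` mode
    the balance check is disabled.  Charge imbalance is only a warning.
    """
    warnings: list[str] = []

    for sp in rxn.substrates + rxn.products:
        if sp.molecule.has_wildcard():
            return ValidationVerdict(False, "underspecified", tuple(warnings))

    if policy.mode == "strict":
        def side_elements(side: tuple[Species, ...]) -> dict[str, int]:
            total: dict[str, int] = {}
            for sp in side:
                for elem, n in _chem.element_counts(sp.molecule.mol).items():
                    total[elem] = total.get(elem, 0) + n * sp.count
            return total

        if side_elements(rxn.substrates) != side_elements(rxn.products):
            return ValidationVerdict(False, "unbalanced", tuple(warnings))

    q_sub = sum(_chem.total_charge(sp.molecule.mol) * sp.count for sp in rxn.substrates)
    q_prod = sum(_chem.total_charge(sp.molecule.mol) * sp.count for sp in rxn.products)
    if q_sub != q_prod:
        warnings.append(f"charge imbalance: {q_sub:+d} -> {q_prod:+d}")

    def side_multiset(side: tuple[Species, ...]) -> tuple[str, ...]:
        out: list[str] = []
        for sp in side:
            smi = sp.molecule.canonical_smiles(keep_stereo=policy.stereo_enabled)
            out.extend([smi] * sp.count)
        return tuple(sorted(out))

    if side_multiset(rxn.substrates) == side_multiset(rxn.products):
        return ValidationVerdict(False, "no-change", tuple(warnings))

    return ValidationVerdict(True, "ok", tuple(warnings))


@dataclasses.dataclass(frozen=True)
class TsvRecord:
    """One row of a reaction TSV: either a parsed reaction or a parse failure."""

    reaction_id: str
    reaction: Optional[MappedReaction]
    error: Optional[str] = None


def read_reactions_tsv(path: Union[str, Path]) -> list[TsvRecord]:
    """Read the ``id<TAB>reaction<TAB>ec;ec<TAB>seq;seq`` dialect.

    Rows whose reaction field is empty or unparseable are returned as failed
    records (downstream they become ``missing-structure`` verdicts) rather
    than aborting the run.
    """
    records: list[TsvRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        rid = fields[0].strip() or f"line{lineno}"
        text = fields[1].strip() if len(fields) > 1 else ""
        ecs = tuple(x for x in (fields[2].split(";") if len(fields) > 2 else []) if x.strip())
        seqs = tuple(x for x in (fields[3].split(";") if len(fields) > 3 else []) if x.strip())
        if not text:
            records.append(TsvRecord(rid, None, "missing reaction string"))
            continue
        try:
            records.append(TsvRecord(rid, parse_mapped_reaction(text, rid, ecs, seqs)))
        except (ReactionParseError, MappingError) as exc:
            records.append(TsvRecord(rid, None, str(exc)))
    return records


def write_reactions_tsv(reactions: Iterable[MappedReaction], path: Union[str, Path]) -> None:
    lines = []
    for rxn in reactions:
        lines.append("\t".join([
            rxn.reaction_id,
            rxn.to_string(),
            ";".join(rxn.ec_numbers),
            ";".join(rxn.sequence_ids),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
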