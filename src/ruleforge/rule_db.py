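"""SQLite persistence of reaction rules.

Schema (13 tables).  At the centre sits ``rules``, keyed by
``(reaction_id, substrate_id, diameter, isStereo)``; each row references a
single SMARTS and SMILES description, bridged bidirectionally through
``smarts_smiles``.  ``rule_products`` holds the one-to-many product list
with stoichiometry.  ``reactions``/``chemical_species`` with their
``reaction_substrates``/``reaction_products`` bridges carry the parsed
source metadata; ``reaction_ec``, ``reaction_sequences``, ``cofactor_log``
and ``run_metadata`` hold annotations and provenance.  The diameter column
stores -1 for the untruncated ("max") rule set; species_id equals the
canonical structure string (fragment patterns are flagged ``is_fragment``).
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from collections.abc import Iterable, Sequence
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from rdkit import Chem

from . import _chem
from .errors import ExportError, QueryError
from .reaction_io import MappedReaction
from .rule_engine import ReactionRule
from .scoring import RuleScore

_SCHEMA = """
PRAGMA foreign_keys = ON;

CREATE TABLE chemical_species (
    species_id   TEXT PRIMARY KEY,
    smiles       TEXT NOT NULL,
    inchi        TEXT,
    is_fragment  INTEGER NOT NULL DEFAULT 0 CHECK (is_fragment IN (0, 1))
);

CREATE TABLE reactions (
    reaction_id   TEXT PRIMARY KEY,
    mapped_smiles TEXT,
    direction     TEXT NOT NULL DEFAULT 'forward'
);

CREATE TABLE reaction_substrates (
    reaction_id   TEXT NOT NULL REFERENCES reactions(reaction_id),
    species_id    TEXT NOT NULL REFERENCES chemical_species(species_id),
    stoichiometry INTEGER NOT NULL,
    PRIMARY KEY (reaction_id, species_id)
);

CREATE TABLE reaction_products (
    reaction_id   TEXT NOT NULL REFERENCES reactions(reaction_id),
    species_id    TEXT NOT NULL REFERENCES chemical_species(species_id),
    stoichiometry INTEGER NOT NULL,
    PRIMARY KEY (reaction_id, species_id)
);

CREATE TABLE reaction_ec (
    reaction_id TEXT NOT NULL REFERENCES reactions(reaction_id),
    ec_number   TEXT NOT NULL,
    PRIMARY KEY (reaction_id, ec_number)
);

CREATE TABLE reaction_sequences (
    reaction_id TEXT NOT NULL REFERENCES reactions(reaction_id),
    sequence_id TEXT NOT NULL,
    PRIMARY KEY (reaction_id, sequence_id)
);

CREATE TABLE smarts (
    smarts_id     INTEGER PRIMARY KEY,
    smarts_string TEXT NOT NULL UNIQUE
);

CREATE TABLE smiles (
    smiles_id     INTEGER PRIMARY KEY,
    smiles_string TEXT NOT NULL UNIQUE
);

CREATE TABLE smarts_smiles (
    smarts_id INTEGER NOT NULL REFERENCES smarts(smarts_id),
    smiles_id INTEGER NOT NULL REFERENCES smiles(smiles_id),
    PRIMARY KEY (smarts_id, smiles_id)
);

CREATE TABLE rules (
    reaction_id      TEXT NOT NULL REFERENCES reactions(reaction_id),
    substrate_id     TEXT NOT NULL REFERENCES chemical_species(species_id),
    diameter         INTEGER NOT NULL,
    isStereo         BOOLEAN NOT NULL CHECK (isStereo IN (0, 1)),
    direction        TEXT NOT NULL,
    smarts_id        INTEGER NOT NULL REFERENCES smarts(smarts_id),
    smiles_id        INTEGER NOT NULL REFERENCES smiles(smiles_id),
    score            REAL,
    n_sequences      INTEGER,
    score_provenance TEXT,
    PRIMARY KEY (reaction_id, substrate_id, diameter, isStereo)
);

CREATE TABLE rule_products (
    reaction_id   TEXT NOT NULL,
    substrate_id  TEXT NOT NULL,
    diameter      INTEGER NOT NULL,
    isStereo      BOOLEAN NOT NULL,
    product_id    TEXT NOT NULL REFERENCES chemical_species(species_id),
    stoichiometry INTEGER NOT NULL,
    PRIMARY KEY (reaction_id, substrate_id, diameter, isStereo, product_id),
    FOREIGN KEY (reaction_id, substrate_id, diameter, isStereo)
        REFERENCES rules(reaction_id, substrate_id, diameter, isStereo)
);

CREATE TABLE cofactor_log (
    reaction_id TEXT NOT NULL REFERENCES reactions(reaction_id),
    species_id  TEXT NOT NULL,
    PRIMARY KEY (reaction_id, species_id)
);

CREATE TABLE run_metadata (
    key   TEXT PRIMARY KEY,
    value TEXT
);
"""

_MAX_DIAMETER_CODE = -1


def _encode_diameter(d: Optional[int]) -> int:
    return _MAX_DIAMETER_CODE if d is None else d


def _decode_diameter(d: int) -> Optional[int]:
    return None if d == _MAX_DIAMETER_CODE else d


class RuleDatabase:
    """Handle on an exported rules database."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)

    def connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.path)
        conn.execute("PRAGMA foreign_keys = ON")
        return conn

    # -- scoring helpers ----------------------------------------------------
    def lookup_score(self, rule_smarts: str, diameter: Optional[int],
                     is_stereo: bool) -> Optional[tuple[float, int]]:
        with self.connect() as conn:
            row = conn.execute(
                """SELECT r.score, r.n_sequences FROM rules r
                   JOIN smarts s ON s.smarts_id = r.smarts_id
                   WHERE s.smarts_string = ? AND r.diameter = ? AND r.isStereo = ?
                   ORDER BY r.score LIMIT 1""",
                (rule_smarts, _encode_diameter(diameter), int(is_stereo))).fetchone()
        if row is None or row[0] is None:
            return None
        return float(row[0]), int(row[1] or 0)

    def worst_penalty_at(self, diameter: Optional[int]) -> Optional[float]:
        with self.connect() as conn:
            row = conn.execute(
                "SELECT MAX(score) FROM rules WHERE diameter = ?",
                (_encode_diameter(diameter),)).fetchone()
        return None if row is None or row[0] is None else float(row[0])

    # -- read-back ----------------------------------------------------------
    def read_rules(self) -> list[ReactionRule]:
        with self.connect() as conn:
            rows = conn.execute(
                """SELECT r.reaction_id, r.substrate_id, r.diameter, r.isStereo,
                          r.direction, sm.smarts_string, sl.smiles_string,
                          r.score, r.n_sequences, r.score_provenance
                   FROM rules r
                   JOIN smarts sm ON sm.smarts_id = r.smarts_id
                   JOIN smiles sl ON sl.smiles_id = r.smiles_id
                   ORDER BY r.reaction_id, r.substrate_id, r.diameter, r.isStereo
                """).fetchall()
            prod_rows = conn.execute(
                """SELECT reaction_id, substrate_id, diameter, isStereo,
                          product_id, stoichiometry
                   FROM rule_products ORDER BY rowid""").fetchall()
        prods: dict[tuple, list[tuple[str, int]]] = {}
        with self.connect() as conn:
            frag_smiles = dict(conn.execute(
                "SELECT species_id, smiles FROM chemical_species").fetchall())
        for rid, sid, d, st, pid, stoich in prod_rows:
            prods.setdefault((rid, sid, d, st), []).append((frag_smiles[pid], stoich))
        out = []
        for rid, sid, d, st, direction, smarts, smiles, score, n_seq, prov in rows:
            out.append(ReactionRule(
                reaction_id=rid,
                parent_reaction_id=rid[:-4] if rid.endswith("_rev") else rid,
                substrate_id=sid, diameter=_decode_diameter(d),
                is_stereo=bool(st), direction=direction,
                rule_smarts=smarts, rule_smiles=smiles,
                products=tuple(prods.get((rid, sid, d, st), ())),
                score=score, n_sequences=n_seq, score_provenance=prov))
        return out

    def content_digest(self) -> str:
        """Deterministic digest of the database content (not the file bytes)."""
        h = hashlib.sha256()
        with self.connect() as conn:
            tables = [r[0] for r in conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name")]
            for table in tables:
                h.update(table.encode())
                cols = [c[1] for c in conn.execute(f"PRAGMA table_info({table})")]
                rows = sorted(repr(r) for r in conn.execute(
                    f"SELECT {', '.join(cols)} FROM {table}"))
                for row in rows:
                    h.update(row.encode())
        return h.hexdigest()

    def integrity_ok(self) -> bool:
        with self.connect() as conn:
            ok = conn.execute("PRAGMA integrity_check").fetchone()[0] == "ok"
            fk = conn.execute("PRAGMA foreign_key_check").fetchall()
        return ok and not fk


def _try_inchi(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return None
    try:
        return Chem.MolToInchi(mol)
    except Exception:  # pragma: no cover - inchi edge cases
        return None


def export_db(rules: Sequence[ReactionRule], scores: Sequence[RuleScore],
              meta: Sequence[MappedReaction], path: Union[str, Path],
              *, run_info: Optional[dict] = None) -> RuleDatabase:
    """Write rules, scores and source metadata to a fresh SQLite file.

    Duplicate rule keys are an error naming the offending key; the written
    file passes SQLite integrity and foreign-key checks and reads back
    value-identically.
    """
    from .scoring import attach_scores  # local import to avoid cycle at import time
    if scores:
        rules = attach_scores(list(rules), list(scores))

    seen: set[tuple] = set()
    for rule in rules:
        if rule.key in seen:
            raise ExportError(f"duplicate rule key {rule.key!r}")
        seen.add(rule.key)

    path = Path(path)
    if path.exists():
        path.unlink()
    try:
        conn = sqlite3.connect(path)
    except sqlite3.Error as exc:  # pragma: no cover - unwritable path
        raise ExportError(f"cannot open {path}: {exc}") from exc

    try:
        conn.executescript(_SCHEMA)

        species: dict[str, tuple[str, Optional[str], int]] = {}

        def add_species(species_id: str, smiles: str, is_fragment: bool) -> None:
            if species_id not in species:
                inchi = None if is_fragment else _try_inchi(smiles)
                species[species_id] = (smiles, inchi, int(is_fragment))

        reactions_rows = []
        bridge_sub, bridge_prod, ec_rows, seq_rows, cof_rows = [], [], [], [], []
        for rxn in meta:
            reactions_rows.append((rxn.reaction_id, rxn.to_string(), rxn.direction_label))
            for bridge, side in ((bridge_sub, rxn.substrates), (bridge_prod, rxn.products)):
                for sp in side:
                    sid = sp.molecule.canonical_smiles()
                    add_species(sid, sid, False)
                    bridge.append((rxn.reaction_id, sid, sp.count))
            for ec in rxn.ec_numbers:
                ec_rows.append((rxn.reaction_id, ec))
            for acc in rxn.sequence_ids:
                seq_rows.append((rxn.reaction_id, acc))

        known_rxn_ids = {r[0] for r in reactions_rows}
        for rule in rules:
            if rule.reaction_id not in known_rxn_ids:
                reactions_rows.append((rule.reaction_id, None, rule.direction))
                known_rxn_ids.add(rule.reaction_id)
            add_species(rule.substrate_id, rule.substrate_id, False)
            for pat, _ in rule.products:
                add_species(pat, pat, True)

        smarts_ids: dict[str, int] = {}
        smiles_ids: dict[str, int] = {}
        for rule in sorted(rules, key=lambda r: r.rule_smarts):
            smarts_ids.setdefault(rule.rule_smarts, len(smarts_ids) + 1)
        for rule in sorted(rules, key=lambda r: r.rule_smiles):
            smiles_ids.setdefault(rule.rule_smiles, len(smiles_ids) + 1)

        conn.executemany(
            "INSERT INTO chemical_species VALUES (?, ?, ?, ?)",
            [(sid, *vals) for sid, vals in sorted(species.items())])
        conn.executemany("INSERT INTO reactions VALUES (?, ?, ?)",
                         sorted(reactions_rows))
        conn.executemany("INSERT INTO reaction_substrates VALUES (?, ?, ?)",
                         sorted(set(bridge_sub)))
        conn.executemany("INSERT INTO reaction_products VALUES (?, ?, ?)",
                         sorted(set(bridge_prod)))
        conn.executemany("INSERT INTO reaction_ec VALUES (?, ?)", sorted(set(ec_rows)))
        conn.executemany("INSERT INTO reaction_sequences VALUES (?, ?)",
                         sorted(set(seq_rows)))
        conn.executemany("INSERT INTO smarts VALUES (?, ?)",
                         sorted((v, k) for k, v in smarts_ids.items()))
        conn.executemany("INSERT INTO smiles VALUES (?, ?)",
                         sorted((v, k) for k, v in smiles_ids.items()))
        pair_rows = sorted({(smarts_ids[r.rule_smarts], smiles_ids[r.rule_smiles])
                            for r in rules})
        conn.executemany("INSERT INTO smarts_smiles VALUES (?, ?)", pair_rows)

        rule_rows, product_rows = [], []
        for rule in sorted(rules, key=lambda r: (r.reaction_id, r.substrate_id,
                                                 _encode_diameter(r.diameter),
                                                 r.is_stereo)):
            rule_rows.append((
                rule.reaction_id, rule.substrate_id, _encode_diameter(rule.diameter),
                int(rule.is_stereo), rule.direction,
                smarts_ids[rule.rule_smarts], smiles_ids[rule.rule_smiles],
                rule.score, rule.n_sequences, rule.score_provenance))
            for pat, stoich in rule.products:
                product_rows.append((
                    rule.reaction_id, rule.substrate_id,
                    _encode_diameter(rule.diameter), int(rule.is_stereo), pat, stoich))
        try:
            conn.executemany(
                "INSERT INTO rules VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)", rule_rows)
        except sqlite3.IntegrityError as exc:
            raise ExportError(f"rules constraint violation: {exc}") from exc
        conn.executemany("INSERT INTO rule_products VALUES (?, ?, ?, ?, ?, ?)",
                         product_rows)

        info = dict(run_info or {})
        for rid, sid in sorted(info.pop("removed_cofactors", [])):
            cof_rows.append((rid, sid))
        conn.executemany("INSERT INTO cofactor_log VALUES (?, ?)", sorted(set(cof_rows)))
        conn.executemany("INSERT INTO run_metadata VALUES (?, ?)",
                         sorted((str(k), json.dumps(v)) for k, v in info.items()))
        conn.commit()
    finally:
        conn.close()
    return RuleDatabase(path)


def query_rules(db: RuleDatabase, *, ec: Optional[str] = None,
                reaction_id: Optional[str] = None,
                substrate: Optional[str] = None,
                min_diameter: Optional[int] = None,
                max_diameter: Optional[int] = None,
                is_stereo: Optional[bool] = None) -> pd.DataFrame:
    """Ranked rule search (best = lowest penalty first).

    ``substrate`` is a SMILES or InChI structure matched by canonical
    structure-string equality against rule substrates.  Diameter bounds are
    inclusive and ignore the untruncated (-1 coded) rule set unless no
    bounds are given.  Ties are broken deterministically by rule key.
    """
    clauses, params = [], []
    if ec is not None:
        clauses.append(
            "r.reaction_id IN (SELECT reaction_id FROM reaction_ec WHERE ec_number = ?)"
            " OR r.reaction_id IN (SELECT reaction_id || '_rev' FROM reaction_ec"
            " WHERE ec_number = ?)")
        params += [ec, ec]
    if reaction_id is not None:
        clauses.append("(r.reaction_id = ? OR r.reaction_id = ?)")
        params += [reaction_id, reaction_id + "_rev"]
    if substrate is not None:
        if substrate.startswith("InChI="):
            mol = Chem.MolFromInchi(substrate)
        else:
            mol = Chem.MolFromSmiles(substrate)
        if mol is None:
            raise QueryError(f"unparseable structure query {substrate!r}")
        clauses.append("r.substrate_id = ?")
        params.append(_chem.canonical_smiles(mol, keep_maps=False))
    if min_diameter is not None:
        clauses.append("r.diameter >= ?")
        params.append(min_diameter)
    if max_diameter is not None:
        clauses.append("(r.diameter <= ? AND r.diameter >= 0)")
        params.append(max_diameter)
    if is_stereo is not None:
        clauses.append("r.isStereo = ?")
        params.append(int(is_stereo))

    where = (" WHERE " + " AND ".join(f"({c})" for c in clauses)) if clauses else ""
    sql = f"""
        SELECT r.reaction_id, r.substrate_id, r.diameter, r.isStereo,
               r.direction, sm.smarts_string AS rule_smarts,
               sl.smiles_string AS rule_smiles, r.score, r.n_sequences,
               r.score_provenance
        FROM rules r
        JOIN smarts sm ON sm.smarts_id = r.smarts_id
        JOIN smiles sl ON sl.smiles_id = r.smiles_id
        {where}
        ORDER BY r.score ASC, r.reaction_id, r.substrate_id, r.diameter, r.isStereo
    """
    with db.connect() as conn:
        frame = pd.read_sql_query(sql, conn, params=params)
    return frame


def rules_frame_to_csv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, index=False)


def rules_frame_to_json(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
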