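"""End-to-end orchestration: validate -> center -> decompose -> extract -> score.

The pipeline is deterministic: given the same reactions, policy and
cofactor list it produces byte-identical rule tables (all orderings are
canonical, no wall-clock state is recorded).
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import Optional, Union

from .reaction_center import augment_stereo, identify_reaction_center
from .reaction_io import (CofactorList, MappedReaction, RunPolicy,
                          ValidationVerdict, validate_reaction)
from .rule_engine import MonoComponent, ReactionRule, decompose, extract_rule
from .scoring import RuleScore, attach_scores, score_rules

import logging

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    policy: RunPolicy
    verdicts: dict[str, ValidationVerdict]
    components: list[MonoComponent]
    rules: list[ReactionRule]          # scored
    scores: list[RuleScore]
    removed_cofactors: list[tuple[str, str]]

    @property
    def accepted_ids(self) -> list[str]:
        return sorted(rid for rid, v in self.verdicts.items() if v.accepted)


def run_pipeline(reactions: Sequence[MappedReaction], policy: RunPolicy,
                 cofactors: Optional[CofactorList] = None,
                 annotations: Optional[Mapping[str, Iterable[str]]] = None,
                 ) -> PipelineResult:
    """Run the full rule-generation procedure over ``reactions``.

    ``annotations`` (reaction id -> sequence accessions) defaults to the
    accessions carried by the reactions themselves.
    """
    if cofactors is None:
        cofactors = CofactorList.default() if policy.cofactor_removal else CofactorList()
    if annotations is None:
        annotations = {r.reaction_id: r.sequence_ids for r in reactions}

    verdicts: dict[str, ValidationVerdict] = {}
    components: list[MonoComponent] = []
    rules: list[ReactionRule] = []
    removed: list[tuple[str, str]] = []
    seen_keys: set[tuple] = set()

    for rxn in reactions:
        verdict = validate_reaction(rxn, policy)
        if verdict.accepted:
            center = identify_reaction_center(rxn)
            if policy.stereo_enabled:
                center = augment_stereo(rxn, center)
            if not center:
                verdict = ValidationVerdict(False, "no-change", verdict.warnings)
        verdicts[rxn.reaction_id] = verdict
        if not verdict.accepted:
            continue

        rxn_components = decompose(rxn, center, cofactors, policy)
        components.extend(rxn_components)
        for comp in rxn_components:
            for smi in comp.removed_cofactors:
                removed.append((comp.rule_reaction_id, smi))
            for diameter in policy.diameters:
                rule = extract_rule(comp, diameter, policy.stereo_enabled)
                if rule is None:
                    continue
                if rule.key in seen_keys:
                    logger.warning("duplicate rule key %s skipped", rule.key)
                    continue
                seen_keys.add(rule.key)
                rules.append(rule)

    scores = score_rules(rules, annotations)
    rules = attach_scores(rules, scores)
    return PipelineResult(policy=policy, verdicts=verdicts, components=components,
                          rules=rules, scores=scores,
                          removed_cofactors=sorted(set(removed)))


_TSV_COLUMNS = ("reaction_id", "substrate_id", "diameter", "is_stereo", "direction",
                "score", "n_sequences", "score_provenance", "rule_smarts",
                "rule_smiles", "products")


def _diameter_str(d: Optional[int]) -> str:
    return "max" if d is None else str(d)


def rules_to_tsv(rules: Iterable[ReactionRule], path: Union[str, Path]) -> None:
    """Write rules to a deterministic TSV (sorted by rule key)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    def sort_key(r: ReactionRule):
        return (r.reaction_id, r.substrate_id, r.diameter is None, r.diameter or 0,
                r.is_stereo)
    for r in sorted(rules, key=sort_key):
        lines.append("\t".join([
            r.reaction_id, r.substrate_id, _diameter_str(r.diameter),
            str(int(r.is_stereo)), r.direction,
            "" if r.score is None else f"{r.score:.6f}",
            "" if r.n_sequences is None else str(r.n_sequences),
            r.score_provenance or "",
            r.rule_smarts, r.rule_smiles,
            json.dumps(r.products),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rules_tsv(path: Union[str, Path]) -> list[ReactionRule]:
    """Read back a rules TSV (pattern fragments are not reconstructed)."""
    text = Path(path).read_text().splitlines()
    header = text[0].split("\t")
    assert header == list(_TSV_COLUMNS), f"unexpected rules TSV header {header}"
    out: list[ReactionRule] = []
    for line in text[1:]:
        if not line.strip():
            continue
        (rid, sid, diameter, stereo, direction, score, n_seq, prov,
         smarts, smiles, products) = line.split("\t")
        out.append(ReactionRule(
            reaction_id=rid,
            parent_reaction_id=rid[:-4] if rid.endswith("_rev") else rid,
            substrate_id=sid,
            diameter=None if diameter == "max" else int(diameter),
            is_stereo=bool(int(stereo)),
            direction=direction,
            rule_smarts=smarts, rule_smiles=smiles,
            products=tuple((p, n) for p, n in json.loads(products)),
            score=float(score) if score else None,
            n_sequences=int(n_seq) if n_seq else None,
            score_provenance=prov or None,
        ))
    return out


def read_annotations_tsv(path: Union[str, Path]) -> dict[str, tuple[str, ...]]:
    """Read ``reaction_id<TAB>acc;acc`` sequence annotations."""
    out: dict[str, tuple[str, ...]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        accs = tuple(a for a in fields[1].split(";") if a.strip()) if len(fields) > 1 else ()
        out[fields[0].strip()] = accs
    return out
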