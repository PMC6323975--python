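"""Biochemical-uncertainty penalty scores for reaction rules.

A rule generated by many distinct enzyme sequences is biochemically less
certain to be reproduced by any one of them; the penalty is log10(n) where
n is the number of distinct non-redundant sequence accessions over all
parent reactions collapsing onto the same canonical rule at a given
diameter.  Rules without any sequence annotation receive the worst penalty
observed at their diameter (conservative fallback), as do on-the-fly rules
absent from a reference database.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping
from typing import Optional

from .errors import NoReferenceScoreError
from .rule_engine import ReactionRule

PROVENANCE_COMPUTED = "computed"
PROVENANCE_INHERITED = "inherited"
PROVENANCE_WORST_CASE = "worst-case"


@dataclasses.dataclass(frozen=True)
class RuleScore:
    """Penalty score of one rule (keyed like the rules table)."""

    reaction_id: str
    substrate_id: str
    diameter: Optional[int]
    is_stereo: bool
    n_sequences: int
    penalty: float
    provenance: str


def _base_reaction_id(rule: ReactionRule) -> str:
    return rule.parent_reaction_id


def score_rules(rules: Iterable[ReactionRule],
                annotations: Mapping[str, Iterable[str]],
                *,
                group_by_ec: Optional[Mapping[str, Iterable[str]]] = None,
                ) -> list[RuleScore]:
    """Score every rule as log10 of its sequence support.

    Rules are grouped by canonical identity per (diameter, isStereo); n is
    the size of the union of sequence accessions over all parent reactions
    in the group.  Groups with n = 0 inherit the maximum penalty observed
    at their diameter (provenance ``worst-case``), 0.0 if nothing at that
    diameter was annotated.  ``group_by_ec`` optionally widens each group's
    union with the accessions of reactions sharing an EC number with a
    group member (off by default).
    """
    rules = list(rules)
    seq_union: dict[tuple, set[str]] = {}
    for rule in rules:
        accs = set(annotations.get(_base_reaction_id(rule), ()))
        if group_by_ec is not None:
            for ec in group_by_ec.get(_base_reaction_id(rule), ()):
                for rid, rid_ecs in group_by_ec.items():
                    if ec in rid_ecs:
                        accs |= set(annotations.get(rid, ()))
        seq_union.setdefault(rule.canonical_key, set()).update(accs)

    worst_at_diameter: dict[Optional[int], float] = {}
    for key, accs in seq_union.items():
        if accs:
            diameter = key[1]
            penalty = math.log10(len(accs))
            worst_at_diameter[diameter] = max(worst_at_diameter.get(diameter, 0.0), penalty)

    scores: list[RuleScore] = []
    for rule in rules:
        accs = seq_union[rule.canonical_key]
        if accs:
            scores.append(RuleScore(
                rule.reaction_id, rule.substrate_id, rule.diameter, rule.is_stereo,
                n_sequences=len(accs), penalty=math.log10(len(accs)),
                provenance=PROVENANCE_COMPUTED))
        else:
            scores.append(RuleScore(
                rule.reaction_id, rule.substrate_id, rule.diameter, rule.is_stereo,
                n_sequences=0,
                penalty=worst_at_diameter.get(rule.diameter, 0.0),
                provenance=PROVENANCE_WORST_CASE))
    return scores


def attach_scores(rules: list[ReactionRule], scores: list[RuleScore]) -> list[ReactionRule]:
    """Return rules with their matching scores filled in (by rule key)."""
    by_key = {(s.reaction_id, s.substrate_id, s.diameter, s.is_stereo): s for s in scores}
    out = []
    for rule in rules:
        s = by_key[rule.key]
        out.append(rule.with_score(s.penalty, s.n_sequences, s.provenance))
    return out


def score_custom_rule(rule: ReactionRule, db) -> RuleScore:
    """Score an on-the-fly rule against a precomputed database.

    If the canonical rule already exists in ``db`` at the same diameter and
    stereo flag it inherits the stored score; otherwise it receives the
    worst (maximum) penalty stored at that diameter.  An empty reference at
    that diameter is an error.
    """
    stored = db.lookup_score(rule.rule_smarts, rule.diameter, rule.is_stereo)
    if stored is not None:
        penalty, n_seq = stored
        return RuleScore(rule.reaction_id, rule.substrate_id, rule.diameter,
                         rule.is_stereo, n_sequences=n_seq, penalty=penalty,
                         provenance=PROVENANCE_INHERITED)
    worst = db.worst_penalty_at(rule.diameter)
    if worst is None:
        raise NoReferenceScoreError(
            f"no reference scores at diameter {rule.diameter!r}")
    return RuleScore(rule.reaction_id, rule.substrate_id, rule.diameter,
                     rule.is_stereo, n_sequences=0, penalty=worst,
                     provenance=PROVENANCE_WORST_CASE)
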