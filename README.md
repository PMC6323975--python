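# ruleforge

Reaction-rule extraction for metabolic retrosynthesis and enzyme-promiscuity
modelling.

Retrosynthesis workflows enumerate biosynthetic routes by applying *reaction
rules* — generic, substructure-level descriptions of enzymatic
transformations — instead of the literal reactions they were learned from.
How generic a rule is can be tuned: keeping only the atoms within a chosen
**diameter** *d* of the reaction center (a sphere of radius *d*/2 bonds)
yields a family of rules per reaction, from highly permissive (*d* = 2) to
fully specific (*d* = max), mimicking the graded substrate promiscuity of
real enzymes.  `ruleforge` turns atom-mapped biochemical reactions into such
rule families, optionally encoding R/S and E/Z stereochemistry, scores each
rule by its enzyme-sequence support, and persists everything to a queryable
SQLite database.

## What it computes

Given a reaction with a full atom-atom mapping (AAM):

1. **Validation** — reactions that transform nothing (passive transport),
   are unbalanced (strict mode), or contain R-group wildcards are rejected
   with a reason code.
2. **Reaction center** — the set of mapped atoms whose bonding environment
   (incident bond multiset, formal charge, or existence) differs between
   the two sides.  In stereo mode, tetrahedral atoms whose R/S descriptor is
   created, inverted or deleted and both atoms of every E/Z-switching double
   bond are added to the reacting set.
3. **Decomposition** — every multi-substrate reaction is split into
   mono-substrate components, one per non-cofactor substrate and per
   direction (rules are generated for both directions); each component keeps
   the products sharing at least one mapped atom with its substrate.
   Ubiquitous cofactors (water, CO2, ATP, NAD(P), ions, ...) are excluded —
   there is no gain in modelling promiscuity on them.
4. **Rule SMARTS generation** — for each component and each even diameter
   *d*, the atoms outside the radius-*d*/2 sphere around the reacting atoms
   are removed and the remainder is written as a canonical reaction SMARTS
   (executable with RDKit) plus a fragment reaction SMILES.
5. **Scoring** — each rule gets the penalty `log10(n)`, where `n` is the
   number of distinct enzyme sequence accessions over all reactions that
   generate the same canonical rule at that diameter; lower is more certain.
   Unannotated and unknown on-the-fly (DIY) rules conservatively inherit the
   worst penalty at their diameter.
6. **Persistence** — rules, products, SMARTS/SMILES strings, source
   reactions, species and annotations go into a single SQLite file keyed by
   `(reaction_id, substrate_id, diameter, isStereo)`, with ranked query and
   CSV/JSON export.

A *DIY* (on-the-fly) mode handles user reactions that are unbalanced or
should keep every species as a primary compound.

## Worked example

The built-in corpus contains a toy tyrosine-aminotransferase reaction
(EC 2.6.1.5): 4-hydroxyphenylpyruvate + L-glutamate -> L-tyrosine +
2-oxoglutarate, mapped so that the keto C/O and amine C/N are the four
reacting atoms.

```python
import ruleforge as rf

corpus = rf.generate_corpus(seed=42, n_variants=3)
policy = rf.RunPolicy(mode="strict", stereo_enabled=False, diameters=(0, 4, None))
result = rf.run_pipeline(corpus.reactions, policy)

hpp = corpus.reaction("TRANS1").substrates[0].molecule.canonical_smiles()
rules = {r.diameter: r for r in result.rules
         if r.reaction_id == "TRANS1" and r.substrate_id == hpp}
```

The diameter-0 rule keeps only the keto group itself:

```
([#6&A&+0&H0:1]=[#8&A&+0&H0&D1&!R:2])>>([#6&A&+0&H1:1]-[#7&A&+0&H2:3]. ...)
```

with score 1.146 (`n` = 14: at low diameter the parent and its three
ring-substituted analog reactions collapse onto one canonical rule, so the
10 parent accessions and 4 analog accessions pool).  The untruncated rule
asserts the whole substrate including ring degree constraints and scores
1.000 (`n` = 10, the parent's own accessions).  Promiscuity follows:

```python
analog = "Oc1ccc(CC(=O)C(=O)O)c(F)c1"        # ring-fluorinated analog
rf.apply_rule(rules[4], analog)
# {('NC(Cc1ccc(O)cc1F)C(=O)O', 'O=C(O)CCC(=O)C(=O)O')}  -- fluoro-tyrosine
rf.apply_rule(rules[None], analog)
# frozenset()                                 -- the specific rule refuses
```

The diameter-4 rule transaminates the analog it has never seen, emitting
the correspondingly fluorinated amino acid and the complete 2-oxoglutarate
co-product; the max-diameter rule only accepts its native substrate.

## Command line

```bash
ruleforge fixtures --seed 42 --out work/              # toy corpus TSV
ruleforge validate --input work/reactions.tsv --mode strict
ruleforge extract  --input work/reactions.tsv --diameters 2,4,8,16,max \
                   --stereo both --out work/rules.tsv
ruleforge score    --rules work/rules.tsv --annotations seqs.tsv \
                   --out work/scored.tsv
ruleforge export   --rules work/scored.tsv --meta work/reactions.tsv \
                   --db work/rules.sqlite
ruleforge query    --db work/rules.sqlite --ec 2.6.1.5 --min-diameter 6 \
                   --format csv
```

## Acceptance script

`scripts/acceptance.py` regenerates the fixture corpus, runs the complete
pipeline in both stereo modes over diameters {0, 2, ..., 16, max}, applies
every extracted rule back to its source substrate, scores the rules and
exports/re-reads the SQLite database:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This artifact has no numeric acceptance targets, so the JSON output is an
empty object; the run must complete without error and prints the
distinct-rule counts per diameter to stderr.

## Layout

- `src/ruleforge/reaction_io.py` — mapped-reaction parsing, validation,
  cofactor lists, run policies
- `src/ruleforge/reaction_center.py` — reacting-atom identification and
  stereo augmentation
- `src/ruleforge/rule_engine.py` — decomposition, diameter truncation,
  SMARTS generation, rule application
- `src/ruleforge/scoring.py` — log10 sequence-support penalties
- `src/ruleforge/rule_db.py` — SQLite schema, export, ranked queries
- `src/ruleforge/fixtures.py` — deterministic toy corpus with expected
  behaviour annotations
- `docs/methods.md` — model, assumptions, numerical choices, limitations
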