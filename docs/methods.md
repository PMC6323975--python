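# Methods

## The model

A reaction rule is a transformation pattern between one substrate and the
products that inherit at least one of its atoms, truncated to the chemical
neighbourhood of the reaction center.  The approach assumes a correct,
complete atom-atom mapping (AAM) of every input reaction: mapping is
*required input* and never inferred — AAM inference is a separate research
problem, and wrong mappings silently produce wrong centers.

### Reaction center

For each map number present on both sides we compare `(formal charge,
multiset of (neighbour map, bond order))`; any difference marks the atom as
reacting, as does presence on one side only (appearing/disappearing atoms,
which occur in unbalanced DIY inputs).  A bond-order change therefore
contributes both endpoints.  An atom whose only change is its implicit
hydrogen count is *not* a center atom unless its charge or bond multiset
changed — H-count changes on such atoms are consequences of neighbour
changes, and including them would inflate every center.

In stereo mode the center is augmented with tetrahedral atoms whose CIP
descriptor (R/S) is created, inverted or deleted across the reaction and
with both atoms of every double bond whose E/Z descriptor changes.
Descriptor comparison uses CIP codes, not parity tags: parities are
atom-order relative and cannot be compared across two independently written
molecules.  An undefined descriptor on one side against a defined one on
the other counts as creation/deletion.  E/Z augmentation deliberately adds
only the two double-bond atoms; their stereo-determining substituents enter
through the diameter sphere (and through the support rule below).

### Diameter truncation

`diameter d` keeps the substrate atoms within `d/2` bonds of any reacting
atom; bonds crossing the boundary are cut.  `d` must be even; `d = max`
(internally `None`, stored as `-1` in SQLite) keeps everything.  On the
product side we keep (a) atoms mapped to retained substrate atoms and
(b) *incoming* atoms — unmapped or mapped to a co-substrate — **in full**.
Choice (b) is deliberate: atoms mapped to truncated substrate atoms are
carried through automatically when the rule fires (the matcher leaves
unmatched substrate atoms attached), but incoming atoms exist only in the
pattern, so truncating them would emit valence-broken or incomplete
co-products.  With (b), applying any rule to its source substrate
regenerates the recorded products exactly — the round-trip property the
test suite enforces at every diameter.

Stereo mode adds one support rule: every atom whose stereo descriptor
changes keeps its direct neighbours regardless of diameter, because a
tetrahedral parity or double-bond geometry is only writable relative to
those neighbours.  Without it, a racemisation rule at `d = 0` would be an
unwritable single-atom parity flip.  Stereo descriptors that lose a
defining neighbour at the truncation boundary are dropped from the pattern
rather than emitted wrong.

### Atom queries

Emitted SMARTS atoms always assert element, aromaticity and formal charge.
Total hydrogen counts are asserted only on reacting atoms — there they
encode the transformation (protonation, reduction, amination); elsewhere
they would over-constrain and kill generalisation.  Degree and ring
membership are asserted only on *interior* atoms (full heavy-atom
neighbourhood retained): interior constraints make the untruncated rule
exact, while boundary atoms stay permissive so truncated rules generalise.
This interior/boundary split is what produces the promiscuity gradient: a
ring atom that is boundary at `d = 8` accepts a substituted analog, the
same atom interior at `d = 16` rejects it.

### Canonicalisation

Rule identity is the SMARTS string itself, so it must be written
canonically: fragment atoms are renumbered by RDKit canonical ranks
(computed with maps stripped, chirality included), map numbers are
reassigned consecutively in that order (substrate first, then products in
sorted order), and product fragments are sorted by their canonical SMILES.
Two input reactions differing only in atom order produce byte-identical
strings; tie-breaking inside canonical ranking is RDKit's and is fixed per
release.  Degenerate rules (identical sides after canonicalisation — e.g. a
racemisation processed without stereo) are suppressed.

### Application

`apply_rule` runs the SMARTS with RDKit's reaction engine.  Both sides are
wrapped in component grouping `(...)` so disconnected patterns match within
one molecule and multi-product rewrites come back as one molecule split by
connectivity.  Two corrections around RDKit behaviour: rewrites that
sanitise to invalid molecules are discarded with a warning (not an error),
and — because `RunReactants` does not filter matches by chirality — stereo
rules post-filter each product set against the chirality-aware substructure
matches of the reactant template, so an (S)-specific rule never fires on
the (R) substrate or on an undefined center.

### Scoring

`penalty = log10(n)` with `n` the union of distinct sequence accessions
over all parent reactions collapsing onto the same canonical rule at a
given `(diameter, isStereo)`.  `n = 1` gives 0 (a rule traceable to a
single enzyme), `n = 10` gives 1.  Rules with `n = 0` receive the maximum
penalty observed at their diameter (0.0 if nothing at that diameter is
annotated) — the same conservative fallback used for on-the-fly rules
absent from a reference database, which otherwise inherit the stored score
of their canonical twin.  Grouping by EC annotation is available as an
opt-in widening of the union but defaults to off; sequence-identity
clustering ("non-redundant" beyond distinct accessions) is out of scope.

## The fixture corpus

`generate_corpus(seed, n_variants)` builds eleven-plus hand-mapped
reactions covering every code path: the EC 2.6.1.5 transamination (center =
keto C/O + amine C/N, 4 components, 10 accessions), ring-substituted
analogs of it for promiscuity (substituent 4-5 bonds from the center, so
rules up to `d = 8` collapse with the parent and match the analogs while
`d >= 10` rules separate and reject them; accession sets overlap pairwise
to exercise the union), a racemisation and a maleate/fumarate isomerisation
(stereo-only rules), a lactone hydrolysis (water as cofactor), an
esterification (two-substrate decomposition, water co-product), a passive
transport, an R-group reaction and an unbalanced decarboxylation (DIY
only).  The seed only selects which substituents decorate the analogs; the
chemistry and expectations are fixed, and the same seed reproduces the
corpus byte for byte.

What the corpus does *not* emulate: multi-step mappings, tautomer and
protonation-state variation, organometallics, polymers/R-group chemistry
beyond the rejection path, and database-scale redundancy.  A green suite
therefore establishes the correctness of the extraction semantics on
well-formed mapped reactions, not robustness to curation noise in real
metabolic databases, and the absolute rule counts of a full-scale release
are out of reach at desk scale by construction.

## Numerical and design choices

- Balance checking compares element multisets including all hydrogens;
  charge imbalance only warns (curated databases are frequently
  charge-inconsistent at fixed pH conventions).
- "No change" is decided on canonical structure multisets, stereo-aware
  only when the run expresses stereo — a racemisation is "no change"
  without stereo and a real reaction with it.
- Cofactor membership is canonical-structure equality with maps stripped;
  the shipped default list (water, CO2, O2, H2O2, ammonia, phosphate,
  diphosphate, AMP/ADP/ATP, NAD(P)(+/H), common ions) is a stand-in and
  fully user-overridable.
- Reverse-direction rules carry the `_rev` reaction-id suffix so both
  directions coexist under the database's composite primary key.
- The fragment reaction SMILES is a depiction and deduplication aid;
  truncated aromatic environments are written as aromatic (lowercase)
  fragments without kekulisation.  Execution always uses the SMARTS.
- Scores, orderings and database digests contain no wall-clock state; two
  identical runs are byte-identical.

## Limitations

- Tetrahedral R/S and double-bond E/Z only; no axial/planar chirality or
  atropisomerism.
- Stereo comparison relies on RDKit CIP perception; centers RDKit cannot
  assign are treated as undefined.
- Single-step application only — route search belongs to retrosynthesis
  frameworks consuming the exported rules.
- Substrate structure search in the database is exact canonical-string
  matching, not substructure search.
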