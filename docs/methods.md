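# Methods

This note records the models implemented in `uskg`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic fixtures do and do not demonstrate.

## Text structuring

A report is split into clauses at sentence-internal delimiters
(`. , ;` plus the full-width CJK marks `。，；`), each clause is
tokenized, multi-word lexicon terms ("right liver", "substantial echo")
are merged by greedy longest match, and every token is annotated with a
normalized form (lowercase plus an optional lemma table, e.g.
`intrahepatic → liver`) and a tag.  Tags come from the domain lexicon
when the normalized form is listed there and from a pluggable
part-of-speech backend otherwise; a backend failure degrades to the tag
`unk` rather than aborting a whole report.

Design choices:

* **Tokenizer and tagger are pluggable callables.**  Word segmentation is
  language-dependent; the default whitespace tokenizer and
  lexicon/suffix-heuristic tagger suffice for the English-like synthetic
  corpus, and a Chinese segmenter or a statistical tagger can be
  registered without touching the pipeline.
* **Edges never cross clause boundaries.**  The term network links
  concepts at token distance 1 within a clause only: the point of clause
  splitting is to keep syntactic units small, and the extraction rules
  operate per clause.
* **Punctuation does not become a concept** — delimiters only bound
  clauses.
* Indices are 0-based throughout; `token_index` is report-wide,
  `sentence_index` is the clause ordinal.

## Rule-based extraction

The stock rule inventory (see README table) is expressed internally in a
normalized head-slot/body form: every rule has an implicit head slot and
a one- or two-tag body.  Three behaviors required decisions the rule
table alone does not fix:

* **Tail-chaining.**  After a match, scanning re-anchors on the last
  matched concept, and a noun that was just matched as a tail becomes
  head-capable.  This is what turns the clause "liver … blood vessel
  structure show clear" into the chain (liver, has, blood vessel),
  (blood vessel, has, structure), (structure, show, clear), and what
  makes the two printed emissions of the organ–noun–adjective rule fall
  out of a single (head, `has`, noun) transition followed by the
  adjective rule.
* **Verb-relation values.**  The organ–verb–X rule accepts both
  adjectives and nouns in its value slot, with the verb's normalized
  form as the relation.
* **Placeholder heads.**  When a clause's first describable group has no
  organ (or chained noun) before it, the triple is emitted with the
  reserved head `@`.  A clause-initial noun–adjective group supports two
  encodings, selected by the `surface_relation` toggle: the compact form
  `(@, noun, adj)` — the attribute noun acts as the relation, matching
  the way such facts are conventionally displayed — or the decomposed
  form `(@, has, noun)` + `(noun, show, adj)`, which keeps the relation
  vocabulary closed (`has`/`show`) and is therefore the default for the
  synthetic corpus used in completion experiments.  Both are first-class
  and tested; neither is claimed to be the uniquely correct reading.
* **Clause-level status predicates** ("has no normalcy") are kept
  uniformly triadic as `(entity, status, predicate-text)` via an optional
  fifth rule (`rules_with_status()`); `default_rules()` itself returns
  exactly the four stock rules.

`@` is reserved: a real entity may not equal it.

## Synonym resolution

Word vectors are trained by a self-contained skip-gram (default) or CBOW
implementation with negative sampling: sliding window (default one-sided
width 2), unigram^0.75 noise distribution, 5 negatives per positive,
linearly decaying learning rate from 0.05, single-threaded and exactly
reproducible per seed.  Dimension defaults to 32 — ample for corpora of
a few hundred distinct terms.

Grouping is anchor-based: candidate terms are visited in descending
corpus frequency; each unassigned term anchors a group absorbing every
remaining candidate whose cosine similarity to the anchor reaches the
threshold.  The canonical term of a group is its most frequent member
(frequent spellings are the natural category names), with lexicographic
tie-breaks.  The similarity threshold defaults to 0.55: published synonym
tables for this task retain members down to ≈0.59, so the default sits
just below that while still excluding unrelated terms; it is exposed as
configuration.  An alternative design — global pairwise clustering
instead of anchor absorption — would merge chains of moderately similar
terms; anchor-based grouping was chosen because it is deterministic,
order-stable and matches the "pick a category name, attach its variants"
workflow.

Rewriting the knowledge graph replaces every member (head, relation or
tail) by its canonical term; counts, order and provenance are untouched,
and the operation is idempotent.

## Embedding and completion

The embedding is a translation-on-hyperplane model.  Per relation:
a unit normal `w_r` and a translation `d_r`; score
`f = ‖P(e_f) + d_r − P(e_t)‖₂²` with `P(e) = e − (wᵀe)w`.  Training
minimizes the margin-ranking loss `Σ max(0, γ + f(pos) − f(neg))` by
per-sample SGD with uniform head-or-tail corruption.  After every
update: `w_r` is renormalized to unit length, `d_r` is re-projected into
the hyperplane and clipped to unit norm, and touched entity vectors are
clipped to the unit ball.  The in-hyperplane/bounded translation
constraints matter in practice: without them the optimizer satisfies the
margin by inflating `‖d_r‖`, which preserves the pairwise gap but
destroys the ranking of unseen (relation, tail) queries.  Defaults:
margin γ = 1.0, learning rate 0.05, 1 negative per positive, dimension
16, all configurable; runs are deterministic per seed.

The Gaussian proximity kernel is read as the classic
`k(e_i, e_j) = exp(−‖e_i − e_j‖²/(2σ²))` — value 1 at zero distance,
monotonically decreasing, bandwidth σ (default 1.0) controlling the
decay radius.

**Completion score direction.**  The completion score combines the
translation residual with the kernel over the *unprojected* head–tail
distance.  `kgcm_score` offers both combination directions:

* `multiply` — residual × kernel, the literal product form;
* `divide` — residual / kernel = residual · exp(+‖·‖²/(2σ²)), which
  *penalizes* distant candidates.

Under an argmin ranking the product form rewards candidates far from the
tail (a small kernel shrinks their score), which inverts the stated
motivation that nearby, recently described entities are the more
plausible omitted subjects.  `complete_entity` therefore ranks with the
distance-penalizing form by default while `kgcm_score` keeps the product
as its literal default; both are exposed and tested, and the proximity
fixture below demonstrates the difference.

Completion itself rewrites each `@`-headed triple with the candidate
minimizing the score of (candidate, relation, tail).  The default
candidate policy is *report-local*: entities mentioned in earlier
clauses of the same report, in order of first mention, falling back to
the whole vocabulary when nothing usable precedes the clause (whether
the original study restricted candidates this way is unknown; the
corpus-wide policy is available as `candidate_policy="all"`).  Ties
break toward the earlier mention, then candidate order (lexicographic
for the corpus-wide policy).  Placeholder triples are never trained on —
they are inference targets only — and unresolvable queries (unknown
relation or tail, empty candidate set) are left as placeholders and
logged, not raised.

## RDF/OWL representation

Part–whole facts (`has`) map to class/subclass axioms (the part is the
subclass), attribute facts (`show`, `status`) to named individuals typed
by their attribute class, and any other relation to a plain
object-property fact; the mapping is a configurable policy and each SKG
triple yields exactly one ontology element.  Identifiers are sanitized
to IRI-safe local names (spaces → underscores).  Serialization goes
through rdflib with triples inserted in sorted order, so emission is
deterministic and a serialize → parse → serialize cycle is
byte-stable; cyclic `has` hierarchies are reported with the offending
path.  Cardinality restrictions are not generated.

## Evaluation

Precision/recall/F1 are set-based over exact triples, or over heads or
tails only (entity-level scoring, since published extraction scores are
sometimes per entity category); zero denominators yield 0 rather than an
error so tiny fixtures evaluate cleanly.  The extraction index
`η = (v/baseline)·(v/n)` uses the valid-domain count of the fixed
five-domain text-matching reference as the baseline; "valid" is
operationalized as an extracted domain whose root entity appears in the
organ lexicon (a stand-in for expert annotation of validity).  Domains
are connected components of the report graph containing an organ term.

## Synthetic fixtures — what they show and what they do not

* **Report grammar**: five abdominal organ domains, each with
  organ-specific sub-part nouns and planted adjective synonym groups;
  each organ block opens with a full-head state clause and follows with
  sub-part clauses that omit the organ head with probability 0.3 by
  default (the condition used in the recovery experiments).  Every
  report carries its gold term network, gold triples (placeholders
  included) and omission list, so extraction and completion are graded
  against construction, not against another extractor.
* **Planted translation lattice** (default 50 entities, 4 relations,
  dimension 8, noise 0.05): relation normals are mutually orthogonal,
  entities sit at `base + subset-sum of relation offsets` in the
  complementary subspace, so every edge satisfies the translation
  identity with residual at most `(2·noise)²`.  Completion queries are
  edges re-posed as `(@, r, t)` targets; the facts remain in the
  training multiset, emulating the transductive clinical setting where
  the entity omitted in one report is written out fully in others.
  Experiment sizes (400 training triples, ≈20 queries, 200 epochs,
  5 seeds) keep the whole recovery suite at desk scale.
* **Proximity fixture**: per query, a gold head close to the tail and a
  distractor with a slightly *better* translation residual but a large
  off-hyperplane offset.  The distance-penalizing completion score ranks
  the gold head first on every query while the plain residual prefers
  the distractor — isolating exactly the contribution of the proximity
  kernel.

The synthetic language is whitespace-tokenized English-like text with a
closed vocabulary and rigidly templated clauses.  Passing tests
therefore demonstrate the algorithmic contracts (rule semantics,
chaining, placeholder handling, recovery under planted geometry), not
robustness to real clinical narrative: free word order, misspellings,
negation scope, cross-clause anaphora beyond head omission and genuinely
ambiguous attributes are all absent, and no claim is made about
Chinese-language segmentation quality.

## Numerical notes

* Hyperplane normals are validated to unit length within 1e-6;
  projection identities are asserted to 1e-9.
* Cosine similarity raises on zero vectors; the kernel raises on
  non-positive σ.
* Score comparisons in completion use a strict-improvement rule
  (1e-15 slack) so earlier candidates win exact ties deterministically.
* All stochastic components (generators, embedding trainers) consume a
  single integer seed through `numpy.random.default_rng`; identical
  seeds reproduce byte-identical outputs.
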