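# Methods

This note documents the models and procedures implemented in
`clintime`, the defaults that matter, and what the synthetic-data
pipeline does and does not show about real annotation campaigns.

## Annotation model

A document annotation is a set of text-bound entities plus a set of
typed directed relations. Entity labels form a closed vocabulary:
`EVENT` and the TIMEX3 family `Date`, `DocTime`, `Time`, `Duration`,
`Set`, `Quantifier`, `PrePost`. The document creation date line
(`DocTime`) is an entity label of its own, not an attribute. Every
`EVENT` — and only an `EVENT` — carries a document-time tag in
{BEFORE, BEFORE-OVERLAP, OVERLAP, AFTER}, its position relative to the
reported hospital stay. Character offsets are 0-based half-open over
the decoded UTF-8 text, the BRAT standoff convention. Discontinuous
(fragmented) spans are rejected: the schema uses contiguous mentions
only.

Relations use the X/Y reading `BEFORE(X, Y)` = "X entirely before Y",
`CONTAINS(X, Y)` = "Y entirely during X", `OVERLAP` = "X and Y share a
common partition of time", `BEGINS-ON` / `ENDS-ON` = shared start /
shared end. BRAT `Arg1`/`Arg2` map to X/Y in that order. `AFTER(Y, X)`
is accepted on input and normalized to `BEFORE(X, Y)`; duplicates
arising from normalization are collapsed with a warning. In standoff
files the document-time tag is the attribute `DocTimeRel` by default;
the name is configurable because annotation projects differ here.

## Temporal closure

Each relation is translated into strict order constraints on interval
endpoints (strict `<`, reflecting the "entirely" wording; `BEGINS-ON`
and `ENDS-ON` use equality of like endpoints). Intervals are
non-degenerate (`start < end`) by default; a switch admits point
events (`start <= end`). Constraints live in the point algebra over
subsets of {<, =, >}; the "not equal" relation never arises, so every
constraint is convex. For convex point networks, path-consistency
propagation — a Floyd–Warshall-style fixpoint over the composition
table, implemented vectorized in numpy over a bitmask matrix —
computes the minimal network. Entailment of a relation is then a
subset check on the propagated constraint of the relevant endpoint
pair(s), and the closure emits *every* entailed relation type for
every ordered vertex pair (not only the most specific), which is what
closure-based agreement scoring needs. A contradiction (an empty
constraint cell) marks the graph inconsistent; the reported witness is
a greedily minimized edge subset reproducing it.

The propagation is cross-checked in the test suite against an
independent brute-force oracle: every interval's endpoints are assigned
values from an integer grid of size 2n (any weak order of 2n points
embeds into {0..2n-1}), all assignments satisfying the premises are
enumerated exhaustively, and a relation is entailed iff it holds in
every one. Closure and oracle agree exactly on all one- and two-edge
graphs over four intervals, all 125 three-edge chains, and seeded
random four-edge graphs.

`BEGINS-ON` is read as "shared start" (start = start). The alternative
reading — X begins when Y *ends* — exists in the wild; it is not
implemented, only noted.

## Agreement

Entity agreement: for every annotator pair, counts are pooled over the
agreement documents and scored per label with both annotators once as
reference and once as response; the two orientations are averaged,
making the score symmetric. Mention mode requires identical spans and
labels; token mode compares per-token labels and reports two overall
variants — counting unannotated tokens as an agreeing None label (the
headline "overall agreement" number) and restricted to annotated
tokens. A document-time mismatch on otherwise matching EVENTs does not
void the entity match. Corpus scores are means with *population* SD
over annotator pairs. Label/pair combinations where a label never
occurs on either side are excluded from that label's mean rather than
scored as zero.

Relation agreement is closure-aware: with A as response and B as
reference, precision is the fraction of A's asserted (normalized)
edges entailed by B's closure; recall mirrors it with the roles
swapped, so after averaging both orientations precision, recall and F1
coincide. Entities are aligned across annotators by exact span first,
then greedy maximal character overlap (ties to the leftmost start); an
edge touching an entity the other annotator did not mark cannot be
verified in their closure and counts against precision. OVERLAP is
compared as an unordered pair, since its constraints are symmetric.
Documents where any annotator's graph is inconsistent are excluded
from the relation scores with a surfaced count instead of aborting the
corpus run — human-annotated graphs can be contradictory.

Confusion matrices use the overlap alignment; unmatched mentions or
edges land in an explicit None row/column. For relation confusion,
pairs asserted by one side are compared against the *most specific*
relation the other side's closure entails for that pair, with
specificity order BEFORE, BEGINS-ON, ENDS-ON, CONTAINS, OVERLAP
(equal-boundary and containment readings are strictly stronger than
OVERLAP, which they entail for non-degenerate intervals).

Merging annotation variants groups mentions across annotators by span
overlap, emits majority span/label/doctime per group, flags label,
span and doctime conflicts and mentions missing from some annotators,
and unions the relations over the merged ids — the input for a
correction round. Chance-corrected coefficients (kappa, alpha) are out
of scope; agreement is F1-based throughout.

## Reporting

Count tables carry one row per label in schema order plus a total;
percentages are half-up rounded to two decimals, and `validate_stat_table`
re-derives every percentage from the absolute column so internally
inconsistent external tables are flagged (a printed count of 3 against
a printed share of 0.75% of 5759, say, cannot both be right; the
implementation trusts totals). The relation surplus is reported under
two conventions — relations minus entities, and relations minus the
true spanning minimum (entities minus documents) — because "more
relations than necessary" is ambiguous between them.

## Synthetic corpus generator

The generator's purpose is a corpus whose *annotation structure* is
realistic while its text is only schema-faithful: pseudo-clinical
German token streams with real date (`13.05.2019`), clock (`14:30`)
and duration-like surfaces at the corresponding entity spans. Nothing
in the closure/agreement pipeline reads the prose, and the injected
date patterns give the rule-based baseline something to find.

Defaults emulate a small synthetic clinical corpus: 63 documents,
~700 ± 150 tokens each (clipped at 20), 0.13 entities per token
(~5.7k entities), entity labels drawn from the corpus's per-type
counts (with the Time row's count corrected to 43, the only value
consistent with the printed total), relation types drawn from the
corpus's relation mix (~75% CONTAINS, ~12% OVERLAP, ~9% BEFORE,
~2.5% BEGINS-ON, ~1.3% ENDS-ON). Document-time tags are sampled
independently (35% BEFORE, 15% BEFORE-OVERLAP, 40% OVERLAP, 10%
AFTER) — a plausibility choice, as no per-tag distribution is
emulated.

Every entity receives a latent interval with exact `Fraction`
endpoints, so no floating-point tie ever corrupts a derived relation.
Endpoints are globally unique within a document except when an
equality is copied on purpose, so `BEGINS-ON`/`ENDS-ON` never arise by
accident. Documents grow by sequential attachment: each new entity is
linked to an anchor — preferentially an already-placed time expression
(probability 0.6), Quantifiers preferentially to an EVENT — with a
relation type drawn from the type mix, and its interval is constructed
so that the drawn type is exactly the most specific true relation to
the anchor. The asserted gold set is this spanning tree plus each
remaining true pair with probability `sparsity` (default 4e-4, which
puts the corpus relation total slightly above the entity total, the
structure the emulated corpus shows). Connectivity and consistency
hold by construction.

Annotator noise, applied independently per mention: drop with a
per-label miss probability (default 0.05, EVENT 0.10 — missing
annotations dominate, EVENTs most), relabel via a confusion table
(default Date→Duration 0.03, Duration→Date 0.05), and jitter one span
boundary by one token with probability 0.02 (a free parameter that
exists to exercise the overlap-alignment path). Per surviving edge,
the type is rewritten to CONTAINS with probability 0.08, modeling the
observed use of CONTAINS as a residual category; rewrites that would
make the document graph inconsistent are reverted, so simulated
annotators always admit an interval model.

`resample_equivalent_relations` produces, per document, a *different*
sparse subset of the timeline's true relations with provably the same
closure (a random spanning tree over entailed true edges, topped up
until the original assertions are entailed). This realizes the
motivating scenario for closure-aware scoring — two annotators sharing
the timeline but not the edges — and is what the closure-robustness
test runs on 55 shorter documents (160 ± 30 tokens), a size chosen to
keep the repeated closure computations quick.

What passing these tests shows — and does not: the pipeline is exact
on its own semantics (zero noise ⇒ agreement exactly 1.0;
closure-equivalent annotators ⇒ relation F1 exactly 1.0; injected
rates recovered within binomial error). It does not show that real
annotators behave like the noise model: real disagreement includes
guideline misreadings, systematic span conventions, and text-dependent
confusions that a label-level noise table cannot produce.

## Tagger harness

`select_ground_truth` picks one annotator variant per multiply
annotated document uniformly at random (seeded). BIO export uses
whitespace/punctuation tokenization with recorded character spans
(dotted dates and clock times are kept as single tokens); overlapping
spans are resolved longest-first. NER evaluation is token-level over
BIO tags: P/R/F1 micro over non-O tokens, accuracy over all tokens
including O/O agreement. REX evaluation scores asserted edges against
gold (strict by default; a flag admits edges entailed by the gold
closure), with accuracy over ordered candidate pairs within a
50-token window, counting mutual-none pairs. The included rule-based
baseline tags day-month-year / month-year and clock patterns as
Date/Time; it exists to exercise the evaluation path, not to compete
with learned taggers, which are deliberately out of scope.

## Numerical and degenerate-input choices

Zero denominators in precision/recall/accuracy yield 0 with a
degeneracy flag rather than NaN. Percentages round half-up. Confusion
proportions are available both row-normalized and grand-total
normalized (heatmap convention). The point-algebra matrix uses int8
bitmasks; propagation repeats full Floyd–Warshall passes until a
fixpoint, which for these convex networks is reached after one or two
passes. Acceptance-scale runs use documents of a few hundred tokens
where per-document closure is needed repeatedly; the propagation is
O(n³) in entities per document and handles the default 91-entity
documents in tens of milliseconds.

## Known limitations

- Only the five-type relation vocabulary (plus AFTER as syntax) is
  supported, not Allen's full 13 relations.
- BRAT event (E), normalization (N) and note lines are reported and
  skipped, not modeled.
- TIMEX value normalization to ISO 8601 is not performed.
- The generator's text is not fluent clinical language, and its noise
  model is label-level, not lexically conditioned.
- Closure is per document; no cross-document inference.
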