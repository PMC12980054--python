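# clintime

Temporal annotation tooling for clinical text: a TimeML-style data
model with BRAT standoff I/O, interval temporal closure, closure-aware
inter-annotator agreement, corpus statistics, a synthetic annotated-
corpus generator with annotator-noise simulation, and an evaluation
harness for temporal taggers.

## The problem

Clinical narratives (discharge summaries, ward notes) describe what
happened to a patient, but the *order* of those happenings is implicit.
Annotation campaigns therefore mark up temporal **entities** — EVENT
mentions plus the TIMEX3 family (Date, DocTime, Time, Duration, Set,
Quantifier, PrePost) — give every EVENT a document-time tag (BEFORE,
BEFORE-OVERLAP, OVERLAP, AFTER relative to the reported hospital stay),
and connect entities with typed **temporal relations** drawn from a
five-type subset of Allen's interval algebra:

| relation | endpoint semantics |
|---|---|
| BEFORE(X, Y) | end(X) < start(Y) (AFTER(Y, X) is its inverse) |
| CONTAINS(X, Y) | start(X) < start(Y) and end(Y) < end(X) |
| OVERLAP(X, Y) | start(X) < end(Y) and start(Y) < end(X) |
| BEGINS-ON(X, Y) | start(X) = start(Y) |
| ENDS-ON(X, Y) | end(X) = end(Y) |

Annotators are asked to keep each document's graph *connected* while
asserting as few edges as possible — something akin to a minimum
spanning tree over the mentions. Two annotators can then describe the
same timeline through nearly disjoint edge sets, which would wreck a
naive agreement score. The fix is **temporal closure**: translate each
edge into the endpoint constraints above, propagate them to a fixpoint
in the point algebra over {<, =, >}, and emit every relation the
asserted set entails. Pairwise agreement is computed against the other
annotator's closure:

```
P(A | B) = |R_A ∩ closure(R_B)| / |R_A|      R(A | B) = P(B | A)
F1 = 2PR / (P + R)
```

scored per relation type and overall, averaged over both orientations
of every annotator pair, and reported as mean ± SD across pairs.
Entity agreement is plain mean pairwise P/R/F1 at mention level (exact
span + label) or token level. Confusion matrices carry an explicit
*None* category, because missing annotations — not label swaps — are
the dominant disagreement in practice.

Since real clinical corpora are rarely distributable, the package
includes a generator that emulates a synthetic German-style corpus
(63 documents, ~44k tokens, ~5.8k entities) from a latent timeline:
every entity is an interval with exact rational endpoints, asserted
edges are a sparse connected subset of the true relations, and
simulated annotators add missing-annotation, Date↔Duration-confusion,
boundary-jitter, and CONTAINS-as-residual noise.

## Worked example

```python
from clintime import *
from clintime.generate import (GeneratorConfig, NoiseConfig,
                               generate_gold_corpus, simulate_annotator,
                               combine_annotators)

cfg = GeneratorConfig(n_docs=10, tokens_per_doc_mean=400.0, seed=11)
gold, timeline = generate_gold_corpus(cfg)
ann = {a: simulate_annotator(gold, NoiseConfig(), seed=s, annotator_id=a)
       for a, s in [("a1", 101), ("a2", 102), ("a3", 103)]}
corpus = combine_annotators(*ann.values())

ent = entity_agreement(corpus)
rel = relation_agreement(corpus)
print(f"entity IAA  F1 = {ent.overall.f1:.3f} +/- {ent.overall.f1_sd:.3f}")
print(f"relation IAA F1 = {rel.overall.f1:.3f} +/- {rel.overall.f1_sd:.3f}")
conf = entity_confusion(corpus).normalized(by="row")
print(f"Date mistaken for Duration in {conf.loc['Date','Duration']:.1%} of aligned pairs")
```

prints

```
entity IAA  F1 = 0.870 +/- 0.005
relation IAA F1 = 0.829 +/- 0.006
Date mistaken for Duration in 4.3% of aligned pairs
```

Three annotators simulated with the default noise profile agree at
F1 ≈ 0.87 on entities; closure-aware relation agreement is lower but
far above what the sparse asserted edges alone would show. The
confusion matrix recovers the injected Date→Duration mass. With
`NoiseConfig.zero()` every score is exactly 1.0 and both confusion
matrices are diagonal.

The same operations are exposed on the command line:

```bash
clintime generate --seed 3 --n-docs 10 --out gold/
clintime simulate --gold gold/ --seed 5 --annotator ann2 --out sim2/
clintime agree entities --corpus corpus/ --mode mention --out results/
clintime stats --corpus gold/
clintime export-bio --corpus gold/ --out train.conll
clintime eval-pred --pred pred/ --gold gold/ --task ner
```

## Layout

| module | contents |
|---|---|
| `clintime.schema` | entity/relation/document types, validation, AFTER normalization |
| `clintime.brat` | BRAT standoff v1.3 parsing/writing, corpus directory I/O |
| `clintime.closure` | temporal graphs, point-algebra propagation, consistency, closure |
| `clintime.agreement` | pairwise IAA, confusion matrices, annotation merging |
| `clintime.reporting` | count/percentage tables, relation-surplus arithmetic |
| `clintime.generate` | latent-timeline corpus generator, noise simulation |
| `clintime.harness` | BIO/candidate export, ground-truth selection, tagger scoring, rule baseline |
| `clintime.cli` | `clintime` command-line tool |

See `docs/methods.md` for the underlying model, parameter defaults and
known limitations.
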