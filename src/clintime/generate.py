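"""Synthetic annotated-corpus generator with simulated annotator noise.

Documents are pseudo-clinical token streams (German clinical-style
vocabulary, real date/clock patterns at temporal-expression spans) —
fluent prose is deliberately out of scope, because nothing in the
agreement/closure pipeline depends on lexical content. What *is*
modeled carefully:

* entity-label and relation-type frequencies (defaults mirror a small
  synthetic German clinical corpus of 63 documents / ~44k tokens);
* a latent timeline per document: every entity is an interval with
  exact rational endpoints, so the full true relation set is derivable
  without floating-point ties;
* sparse annotation: the asserted edges are a random spanning tree
  over the entities (each new mention linked to an anchor, preferably
  a time expression) plus a small surplus of extra true edges;
* annotator noise dominated by *missing* annotations, plus
  Date<->Duration label confusion, boundary jitter, and the tendency
  to use CONTAINS as a residual relation category.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

from .closure import TemporalGraph, build_graph, compute_closure, propagate
from .schema import (
    AnnotatedCorpus,
    AnnotationError,
    DocumentAnnotation,
    EntityAnnotation,
    RelationAnnotation,
    Span,
    corpus_from_documents,
    normalize_relations,
)

Interval = tuple[Fraction, Fraction]

# Default entity-label distribution (counts of the emulated corpus;
# the printed per-type percentages identify the Time count as 43).
DEFAULT_ENTITY_COUNTS = {
    "Date": 663,
    "DocTime": 92,
    "Time": 43,
    "Duration": 138,
    "Set": 158,
    "Quantifier": 118,
    "PrePost": 24,
    "EVENT": 4523,
}

DEFAULT_RELATION_COUNTS = {
    "BEFORE": 547,
    "BEGINS-ON": 146,
    "ENDS-ON": 74,
    "OVERLAP": 679,
    "CONTAINS": 4352,
}


def _normalize_probs(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class NoiseConfig:
    """Annotator-noise parameters.

    ``miss_prob`` maps entity labels to drop probabilities (``default``
    fills unlisted labels); missing annotations are the dominant error
    mode, EVENTs more than time expressions. ``label_confusion`` maps a
    gold label to relabeling probabilities (Date<->Duration carries the
    characteristic mass). ``contains_residual_prob`` rewrites an
    asserted non-CONTAINS edge to CONTAINS, the residual-category
    habit. ``span_jitter_prob`` moves one mention boundary by one token.
    """

    miss_default: float = 0.05
    miss_prob: dict = field(default_factory=lambda: {"EVENT": 0.10})
    label_confusion: dict = field(
        default_factory=lambda: {
            "Date": {"Duration": 0.03},
            "Duration": {"Date": 0.05},
        }
    )
    contains_residual_prob: float = 0.08
    span_jitter_prob: float = 0.02

    def miss(self, label: str) -> float:
        return self.miss_prob.get(label, self.miss_default)

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(miss_default=0.0, miss_prob={}, label_confusion={},
                   contains_residual_prob=0.0, span_jitter_prob=0.0)


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic corpus.

    Defaults mirror the emulated corpus scale: 63 documents of ~700
    tokens, ~0.13 entities per token, label/relation mixes from the
    default count tables. ``sparsity`` is the probability that a
    non-spanning-tree entity pair gets its true relation asserted too;
    the default makes the corpus relation total land slightly above
    the entity total, as in the emulated corpus. Generation is a pure
    function of the config, including ``seed``.
    """

    n_docs: int = 63
    tokens_per_doc_mean: float = 700.0
    tokens_per_doc_sd: float = 150.0
    entity_rate: float = 0.13
    entity_label_probs: dict = field(
        default_factory=lambda: _normalize_probs(DEFAULT_ENTITY_COUNTS)
    )
    doctime_probs: dict = field(
        default_factory=lambda: {
            "BEFORE": 0.35, "BEFORE-OVERLAP": 0.15, "OVERLAP": 0.40, "AFTER": 0.10,
        }
    )
    relation_type_probs: dict = field(
        default_factory=lambda: _normalize_probs(DEFAULT_RELATION_COUNTS)
    )
    sparsity: float = 0.0004
    anchor_preference: float = 0.6
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("entity_label_probs", self.entity_label_probs),
            ("doctime_probs", self.doctime_probs),
            ("relation_type_probs", self.relation_type_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise AnnotationError(f"{name} must sum to 1")
        if self.entity_rate * max(20.0, self.tokens_per_doc_mean) < 2:
            raise AnnotationError("config yields fewer than 2 entities per document")


@dataclass
class LatentTimeline:
    """Ground-truth interval per entity: doc_id -> entity_id -> (start, end)."""

    intervals: dict[str, dict[str, Interval]] = field(default_factory=dict)

    def write_sidecar(self, path: str | Path) -> None:
        lines = ["doc_id\tentity_id\tstart\tend"]
        for doc_id in sorted(self.intervals):
            for eid, (s, e) in sorted(self.intervals[doc_id].items()):
                lines.append(f"{doc_id}\t{eid}\t{s}\t{e}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def true_relation(
    i: str, j: str, a: Interval, b: Interval
) -> Optional[tuple[str, str, str]]:
    """Most specific of the five relation types holding between two
    latent intervals, in canonical argument order; None for the
    'meets' configuration (shared boundary point between start and
    end), which the vocabulary cannot express."""
    (s1, e1), (s2, e2) = a, b
    if e1 < s2:
        return (i, j, "BEFORE")
    if e2 < s1:
        return (j, i, "BEFORE")
    if s1 == s2 and e1 == e2:
        return (i, j, "BEGINS-ON")
    if s1 == s2:
        return (i, j, "BEGINS-ON")
    if e1 == e2:
        return (i, j, "ENDS-ON")
    if s1 < s2 and e2 < e1:
        return (i, j, "CONTAINS")
    if s2 < s1 and e1 < e2:
        return (j, i, "CONTAINS")
    if s1 < e2 and s2 < e1:
        return (i, j, "OVERLAP")
    return None


def all_true_relations(intervals: dict[str, Interval]) -> set[tuple[str, str, str]]:
    ids = sorted(intervals)
    out = set()
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            r = true_relation(ids[x], ids[y], intervals[ids[x]], intervals[ids[y]])
            if r is not None:
                out.add(r)
    return out


class _Endpoints:
    """Fresh rational endpoint factory; values are globally unique per
    document unless an equality is copied on purpose, so no accidental
    BEGINS-ON/ENDS-ON coincidences corrupt the derived relations."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[Fraction] = set()

    def pick(self, lo: Fraction, hi: Fraction) -> Fraction:
        den = 16
        while True:
            v = lo + (hi - lo) * Fraction(self.rng.randint(1, den - 1), den)
            if v not in self.used and lo < v < hi:
                self.used.add(v)
                return v
            den *= 2

    def reuse(self, v: Fraction) -> Fraction:
        return v


def _place_relative(
    rtype: str,
    anchor: Interval,
    pts: _Endpoints,
    rng: random.Random,
) -> tuple[Interval, bool]:
    """Construct an interval whose most specific relation to ``anchor``
    is ``rtype``. Returns (interval, new_is_arg1): whether the new
    entity plays the X role of the relation."""
    s, e = anchor
    one = Fraction(1)
    if rtype == "BEFORE":
        if rng.random() < 0.5:  # new entirely before anchor
            ns = pts.pick(s - 2 * one, s - one)
            ne = pts.pick(ns, s)
            return (ns, ne), True
        ns = pts.pick(e, e + one)
        ne = pts.pick(ns, e + 2 * one)
        return (ns, ne), False
    if rtype == "CONTAINS":
        if rng.random() < 0.75:  # anchor contains new (the common case)
            ns = pts.pick(s, e)
            ne = pts.pick(ns, e)
            return (ns, ne), False
        ns = pts.pick(s - one, s)
        ne = pts.pick(e, e + one)
        return (ns, ne), True
    if rtype == "OVERLAP":
        first = rng.random() < 0.5
        if rng.random() < 0.5:  # new crosses the left boundary
            ns = pts.pick(s - one, s)
            ne = pts.pick(s, e)
        else:  # new crosses the right boundary
            ns = pts.pick(s, e)
            ne = pts.pick(e, e + one)
        return (ns, ne), first
    if rtype == "BEGINS-ON":
        ns = pts.reuse(s)
        ne = pts.pick(s, e) if rng.random() < 0.5 else pts.pick(e, e + one)
        return (ns, ne), rng.random() < 0.5
    if rtype == "ENDS-ON":
        ne = pts.reuse(e)
        ns = pts.pick(s, e) if rng.random() < 0.5 else pts.pick(s - one, s)
        return (ns, ne), rng.random() < 0.5
    raise AnnotationError(f"unknown relation type {rtype!r}")


# ---------------------------------------------------------------------------
# Token/text synthesis

_FILLER = (
    "Patient Aufnahme Befund stationär Behandlung Anamnese Schmerzen Medikation "
    "Kontrolle Verlauf unauffällig rechts links Herz Lunge Abdomen Labor Diagnose "
    "Beschwerden Symptomatik ambulant empfohlen Fortsetzung Gabe gut stabil ohne "
    "mit und der die das bei nach vor über wurde zeigt erfolgte weiterhin initial "
    "regelrecht deutlich klinisch radiologisch sonographisch"
).split()

_EVENT_WORDS = (
    "Operation Chemotherapie Blutung Infektion Dialyse Transfusion Biopsie "
    "Punktion Revision Sturz Fieber Sepsis Stenose Embolie Reanimation Entlassung "
    "Aufnahme Intubation Anlage Drainage"
).split()

_EVENT_MODIFIERS = "laparoskopische akute rezidivierende postinterventionelle".split()


def _date_tokens(rng: random.Random) -> list[str]:
    return [f"{rng.randint(1, 28):02d}.{rng.randint(1, 12):02d}.{rng.randint(2015, 2023)}"]


def _surface_tokens(label: str, rng: random.Random) -> list[str]:
    if label in ("Date", "DocTime"):
        return _date_tokens(rng)
    if label == "Time":
        return [f"{rng.randint(0, 23):02d}:{rng.randint(0, 59):02d}"]
    if label == "Duration":
        return rng.choice(
            [[f"{rng.randint(2, 14)}", "Tage"], ["seit", f"{rng.randint(2010, 2020)}"],
             ["für", f"{rng.randint(2, 8)}", "Wochen"]]
        )
    if label == "Set":
        return rng.choice([["zweimal", "täglich"], ["wöchentlich"], ["1-0-1"]])
    if label == "Quantifier":
        return rng.choice([["zweiter", "Zyklus"], ["dritte", "Gabe"], ["erste"]])
    if label == "PrePost":
        return [rng.choice(["postoperativ", "präoperativ", "prästationär"])]
    mod = [rng.choice(_EVENT_MODIFIERS)] if rng.random() < 0.25 else []
    return mod + [rng.choice(_EVENT_WORDS)]


def _build_text(
    labels: Sequence[str], rng: random.Random, n_tokens: int
) -> tuple[str, list[EntityAnnotation]]:
    """Lay out entity surfaces over a filler token stream; spans are
    non-overlapping by construction."""
    surfaces = [_surface_tokens(lab, rng) for lab in labels]
    used = sum(len(s) for s in surfaces)
    n_fill = max(0, n_tokens - used)
    n_gaps = len(labels) + 1
    cuts = sorted(rng.randint(0, n_fill) for _ in range(n_gaps - 1))
    gap_sizes = [b - a for a, b in zip([0] + cuts, cuts + [n_fill])]
    tokens: list[str] = []
    placements: list[tuple[int, int, str]] = []  # token start, token end, label idx
    for i, surf in enumerate(surfaces):
        tokens.extend(rng.choice(_FILLER) for _ in range(gap_sizes[i]))
        placements.append((len(tokens), len(tokens) + len(surf), i))
        tokens.extend(surf)
    tokens.extend(rng.choice(_FILLER) for _ in range(gap_sizes[-1]))

    offsets = []
    pos = 0
    for t in tokens:
        offsets.append((pos, pos + len(t)))
        pos += len(t) + 1
    text = " ".join(tokens)
    entities = []
    for t0, t1, i in placements:
        start = offsets[t0][0]
        end = offsets[t1 - 1][1]
        entities.append(
            EntityAnnotation(
                id=f"T{i + 1}",
                label=labels[i],
                span=Span(start, end),
                surface=text[start:end],
            )
        )
    return text, entities


# ---------------------------------------------------------------------------
# Gold corpus generation

def _sample_labels(config: GeneratorConfig, rng: random.Random, n: int) -> list[str]:
    labels = list(config.entity_label_probs)
    weights = [config.entity_label_probs[k] for k in labels]
    return rng.choices(labels, weights=weights, k=n)


def _generate_document(
    config: GeneratorConfig, rng: random.Random, doc_id: str
) -> tuple[DocumentAnnotation, dict[str, Interval]]:
    n_tokens = max(20, round(rng.gauss(config.tokens_per_doc_mean, config.tokens_per_doc_sd)))
    n_entities = max(2, round(config.entity_rate * n_tokens))
    labels = _sample_labels(config, rng, n_entities)
    text, entities = _build_text(labels, rng, n_tokens)
    entities = [
        replace(e, doctime=_weighted(rng, config.doctime_probs)) if e.label == "EVENT" else e
        for e in entities
    ]

    # Latent timeline: sequential attachment, preferring TIMEX anchors
    # ("units of meaning" anchored on time expressions).
    pts = _Endpoints(rng)
    order = list(range(n_entities))
    rng.shuffle(order)
    intervals: dict[str, Interval] = {}
    timex_ids: list[str] = []
    relations: list[RelationAnnotation] = []
    rel_i = 0
    placed: list[str] = []
    for k in order:
        ent = entities[k]
        if not placed:
            s = pts.pick(Fraction(0), Fraction(1))
            e = pts.pick(s, Fraction(2))
            intervals[ent.id] = (s, e)
        else:
            event_ids = [entities[o].id for o in order[: len(placed)]
                         if entities[o].label == "EVENT" and entities[o].id in intervals]
            if ent.label == "Quantifier" and event_ids:
                # Quantifiers count EVENT occurrences; pair them with one.
                target = rng.choice(event_ids)
            elif timex_ids and rng.random() < config.anchor_preference:
                target = rng.choice(timex_ids)
            else:
                target = rng.choice(placed)
            rtype = _weighted(rng, config.relation_type_probs)
            iv, new_is_x = _place_relative(rtype, intervals[target], pts, rng)
            intervals[ent.id] = iv
            rel_i += 1
            a1, a2 = (ent.id, target) if new_is_x else (target, ent.id)
            relations.append(RelationAnnotation(id=f"R{rel_i}", rtype=rtype, arg1=a1, arg2=a2))
        placed.append(ent.id)
        if ent.label in ("Date", "DocTime", "Time"):
            timex_ids.append(ent.id)

    if config.sparsity > 0:
        tree_pairs = {frozenset((r.arg1, r.arg2)) for r in relations}
        ids = [e.id for e in entities]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                pair = frozenset((ids[x], ids[y]))
                if pair in tree_pairs or rng.random() >= config.sparsity:
                    continue
                r = true_relation(ids[x], ids[y], intervals[ids[x]], intervals[ids[y]])
                if r is not None:
                    rel_i += 1
                    relations.append(
                        RelationAnnotation(id=f"R{rel_i}", rtype=r[2], arg1=r[0], arg2=r[1])
                    )

    doc = DocumentAnnotation(
        doc_id=doc_id, annotator_id="gold", text=text, entities=entities, relations=relations
    )
    return doc, intervals


def _weighted(rng: random.Random, probs: dict) -> str:
    keys = list(probs)
    return rng.choices(keys, weights=[probs[k] for k in keys], k=1)[0]


def generate_gold_corpus(config: GeneratorConfig) -> tuple[AnnotatedCorpus, LatentTimeline]:
    """Generate the gold corpus and its latent timeline.

    Every document's relation graph is connected (spanning attachment)
    and consistent (all asserted relations are true of the latent
    intervals). Deterministic in ``config.seed``.
    """
    config.validate()
    rng = random.Random(config.seed)
    timeline = LatentTimeline()
    docs = []
    width = len(str(config.n_docs))
    for i in range(config.n_docs):
        doc_id = f"doc{i + 1:0{width}d}"
        doc, intervals = _generate_document(config, random.Random(rng.getrandbits(31)), doc_id)
        docs.append(doc)
        timeline.intervals[doc_id] = intervals
    return corpus_from_documents(docs), timeline


def agreement_partition(
    doc_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Uniform random split: round(fraction * n) agreement documents,
    the rest production. Deterministic under ``seed``."""
    if not 0 <= fraction <= 1:
        raise AnnotationError("fraction must be in [0, 1]")
    rng = random.Random(seed)
    ids = sorted(doc_ids)
    k = round(fraction * len(ids))
    agreement = sorted(rng.sample(ids, k))
    production = [d for d in ids if d not in set(agreement)]
    return agreement, production


# ---------------------------------------------------------------------------
# Annotator simulation

def _jitter_span(doc_text: str, e: EntityAnnotation, occupied: list[Span], rng: random.Random):
    """Move one boundary of the mention by one token, keeping spans
    inside the text and disjoint from other mentions."""
    from .text import tokenize_text

    tokens = tokenize_text(doc_text)
    starts = [t.start for t in tokens]
    ends = [t.end for t in tokens]
    cands = []
    prev_start = max((ts for ts in starts if ts < e.span.start), default=None)
    next_end = min((te for te in ends if te > e.span.end), default=None)
    if prev_start is not None:
        cands.append(Span(prev_start, e.span.end))  # grow left
    if next_end is not None:
        cands.append(Span(e.span.start, next_end))  # grow right
    inner_starts = [ts for ts in starts if e.span.start < ts < e.span.end]
    if inner_starts:
        cands.append(Span(min(inner_starts), e.span.end))  # shrink left
    inner_ends = [te for te in ends if e.span.start < te < e.span.end]
    if inner_ends:
        cands.append(Span(e.span.start, max(inner_ends)))  # shrink right
    rng.shuffle(cands)
    for c in cands:
        if c.end <= len(doc_text) and all(c.overlap(o) == 0 for o in occupied):
            return c
    return e.span


def simulate_annotator(
    gold: AnnotatedCorpus,
    noise: NoiseConfig,
    seed: int,
    annotator_id: str = "sim",
) -> AnnotatedCorpus:
    """Derive one noisy annotation variant of a gold corpus.

    Mentions are independently dropped, relabeled and jittered;
    asserted edges incident to dropped mentions disappear, and
    surviving edges are rewritten to CONTAINS with
    ``contains_residual_prob``. Rewrites that would make a document's
    graph inconsistent are reverted, so every output graph still
    admits an interval model.
    """
    rng = random.Random(seed)
    out_docs = []
    for doc_id in gold.doc_ids:
        src = gold.get(doc_id, gold.annotators_of(doc_id)[0])
        doc_rng = random.Random(rng.getrandbits(31))
        kept: list[EntityAnnotation] = []
        for e in src.entities:
            if doc_rng.random() < noise.miss(e.label):
                continue
            label = e.label
            conf = noise.label_confusion.get(label, {})
            u = doc_rng.random()
            acc = 0.0
            for to_label, p in conf.items():
                acc += p
                if u < acc:
                    label = to_label
                    break
            doctime = e.doctime
            if label == "EVENT" and doctime is None:
                doctime = doc_rng.choice(["BEFORE", "OVERLAP"])
            if label != "EVENT":
                doctime = None
            kept.append(replace(e, label=label, doctime=doctime))
        if noise.span_jitter_prob > 0:
            jittered = []
            for i, e in enumerate(kept):
                if doc_rng.random() < noise.span_jitter_prob:
                    others = [o.span for j, o in enumerate(kept) if j != i]
                    new_span = _jitter_span(src.text, e, others, doc_rng)
                    e = replace(
                        e, span=new_span, surface=src.text[new_span.start : new_span.end]
                    )
                jittered.append(e)
            kept = jittered
        kept_ids = {e.id for e in kept}

        relations: list[RelationAnnotation] = []
        rewritten: list[tuple[int, str]] = []  # (index, original type)
        for r in normalize_relations(src).relations:
            if r.arg1 not in kept_ids or r.arg2 not in kept_ids:
                continue
            if r.rtype != "CONTAINS" and doc_rng.random() < noise.contains_residual_prob:
                rewritten.append((len(relations), r.rtype))
                r = replace(r, rtype="CONTAINS")
            relations.append(r)

        # Revert residual-category rewrites that broke consistency.
        if rewritten:
            vertices = sorted(kept_ids)

            def consistent(rels: list[RelationAnnotation]) -> bool:
                g = TemporalGraph(vertices=list(vertices), edges={x.edge for x in rels})
                return propagate(g).consistent

            doc_rng.shuffle(rewritten)
            while not consistent(relations) and rewritten:
                idx, orig = rewritten.pop()
                relations[idx] = replace(relations[idx], rtype=orig)

        out_docs.append(
            DocumentAnnotation(
                doc_id=doc_id,
                annotator_id=annotator_id,
                text=src.text,
                entities=kept,
                relations=relations,
            )
        )
    return corpus_from_documents(out_docs, agreement_docs=set(gold.agreement_docs))


# ---------------------------------------------------------------------------
# Closure-equivalent resampling

def resample_equivalent_relations(
    gold: AnnotatedCorpus,
    timeline: LatentTimeline,
    seed: int,
    annotator_id: str = "resampled",
) -> AnnotatedCorpus:
    """Replace each document's asserted edges by a *different* sparse
    subset of the timeline's true relations with the same closure.

    This models the motivating scenario for closure-aware agreement:
    two annotators describe the same underlying timeline through
    different sparse edge sets. The resampled set is a random spanning
    tree over true relations entailed by the gold closure, topped up
    (when the tree alone entails less) until its closure matches.
    """
    rng = random.Random(seed)
    out_docs = []
    for doc_id in gold.doc_ids:
        src = normalize_relations(gold.get(doc_id, gold.annotators_of(doc_id)[0]))
        doc_rng = random.Random(rng.getrandbits(31))
        gold_graph = build_graph(src)
        gold_closure = compute_closure(gold_graph).edges
        intervals = timeline.intervals[doc_id]
        candidates = [
            e for e in sorted(all_true_relations(intervals)) if e in gold_closure
        ]
        # Random spanning tree over candidate edges.
        doc_rng.shuffle(candidates)
        parent = {v: v for v in gold_graph.vertices}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        chosen: list[tuple[str, str, str]] = []
        rest: list[tuple[str, str, str]] = []
        for e in candidates:
            ra, rb = find(e[0]), find(e[1])
            if ra != rb:
                parent[ra] = rb
                chosen.append(e)
            else:
                rest.append(e)

        # Top up until the gold assertions are entailed (then closures
        # coincide: chosen <= gold closure and closure(chosen) >= gold).
        def closure_edges() -> set:
            g = TemporalGraph(vertices=list(gold_graph.vertices), edges=set(chosen))
            return compute_closure(g).edges

        cl = closure_edges()
        missing = [e for e in sorted(gold_graph.edges) if e not in cl]
        doc_rng.shuffle(missing)
        while missing:
            chosen.append(missing.pop())
            cl = closure_edges()
            missing = [e for e in missing if e not in cl]

        relations = [
            RelationAnnotation(id=f"R{i + 1}", rtype=t, arg1=a, arg2=b)
            for i, (a, b, t) in enumerate(chosen)
        ]
        out_docs.append(
            DocumentAnnotation(
                doc_id=doc_id,
                annotator_id=annotator_id,
                text=src.text,
                entities=list(src.entities),
                relations=relations,
            )
        )
    return corpus_from_documents(out_docs, agreement_docs=set(gold.agreement_docs))


def combine_annotators(*corpora: AnnotatedCorpus) -> AnnotatedCorpus:
    """Stack per-annotator corpora into one multi-annotator corpus;
    agreement documents are those covered by every annotator."""
    out = AnnotatedCorpus()
    for c in corpora:
        for doc in c.documents.values():
            out.add(doc)
    n = len(out.annotator_ids)
    out.agreement_docs = {
        d for d in out.doc_ids if len(out.annotators_of(d)) == n
    }
    return out
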