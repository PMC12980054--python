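"""Export, ground-truth selection and evaluation for sequence-labeling
and relation-classification baselines.

The harness defines the data contract (BIO token tags, relation
candidate pairs) and the metrics, so any external tagger's output can
be scored; a small regular-expression time-expression baseline is
included so the evaluation path runs end to end without a trained
model. Transformer fine-tuning itself is out of scope.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .agreement import MatchCounts, compute_accuracy, compute_prf
from .closure import build_graph, compute_closure
from .schema import (
    AnnotatedCorpus,
    AnnotationError,
    DocumentAnnotation,
    EntityAnnotation,
    Span,
    corpus_from_documents,
    normalize_relations,
)
from .text import Token, tokenize_text


def select_ground_truth(corpus: AnnotatedCorpus, seed: int) -> AnnotatedCorpus:
    """One annotation variant per document.

    Documents with a single annotator pass through; for multiply
    annotated (agreement) documents one annotator is chosen uniformly
    at random, deterministically under ``seed``.
    """
    rng = random.Random(seed)
    docs = []
    for doc_id in corpus.doc_ids:
        annotators = corpus.annotators_of(doc_id)
        pick = annotators[0] if len(annotators) == 1 else rng.choice(annotators)
        docs.append(corpus.get(doc_id, pick))
    return corpus_from_documents(docs)


# ---------------------------------------------------------------------------
# BIO encoding

@dataclass
class TokenTagSequence:
    doc_id: str
    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise AnnotationError("tokens and tags differ in length")


def to_bio(doc: DocumentAnnotation, doctime_suffix: bool = False) -> TokenTagSequence:
    """Encode entity spans as BIO tags at token granularity.

    Overlapping entity spans are resolved longest-first. With
    ``doctime_suffix``, EVENT tags carry the document-time tag
    (``B-EVENT:BEFORE``).
    """
    tokens = tokenize_text(doc.text)
    tags = ["O"] * len(tokens)
    for e in sorted(doc.entities, key=lambda e: (-len(e.span), e.span.start)):
        covered = [
            i for i, t in enumerate(tokens)
            if min(t.end, e.span.end) - max(t.start, e.span.start) > 0
        ]
        if not covered or any(tags[i] != "O" for i in covered):
            continue
        name = e.label
        if doctime_suffix and e.label == "EVENT" and e.doctime:
            name = f"{e.label}:{e.doctime}"
        tags[covered[0]] = f"B-{name}"
        for i in covered[1:]:
            tags[i] = f"I-{name}"
    return TokenTagSequence(doc_id=doc.doc_id, tokens=tokens, tags=tags)


def from_bio(seq: TokenTagSequence, text: str, annotator_id: str = "bio") -> DocumentAnnotation:
    """Decode BIO tags back to entities at token granularity."""
    entities: list[EntityAnnotation] = []
    current: Optional[tuple[str, int, int]] = None  # (name, start, end)

    def flush():
        nonlocal current
        if current is None:
            return
        name, s, e = current
        label, _, doctime = name.partition(":")
        entities.append(
            EntityAnnotation(
                id=f"T{len(entities) + 1}",
                label=label,
                span=Span(s, e),
                surface=text[s:e],
                doctime=doctime or ("OVERLAP" if label == "EVENT" else None),
            )
        )
        current = None

    for tok, tag in zip(seq.tokens, seq.tags):
        if tag == "O":
            flush()
        elif tag.startswith("B-"):
            flush()
            current = (tag[2:], tok.start, tok.end)
        elif tag.startswith("I-") and current is not None and current[0] == tag[2:]:
            current = (current[0], current[1], tok.end)
        else:  # stray I- tag: treat as B-
            flush()
            current = (tag[2:], tok.start, tok.end)
    flush()
    return DocumentAnnotation(
        doc_id=seq.doc_id, annotator_id=annotator_id, text=text, entities=entities
    )


def write_conll(corpus: AnnotatedCorpus, doctime_suffix: bool = False) -> str:
    """Two-column token/tag export, blank line between documents."""
    blocks = []
    for doc_id in corpus.doc_ids:
        doc = corpus.get(doc_id, corpus.annotators_of(doc_id)[0])
        seq = to_bio(doc, doctime_suffix=doctime_suffix)
        blocks.append("\n".join(f"{t.text}\t{tag}" for t, tag in zip(seq.tokens, seq.tags)))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# Relation candidates

@dataclass(frozen=True)
class RelationCandidate:
    doc_id: str
    arg1: str
    arg2: str
    label: str  # relation type or "none"


def relation_candidates(
    doc: DocumentAnnotation, max_token_distance: Optional[int] = 50
) -> list[RelationCandidate]:
    """Ordered within-document entity pairs, labeled with the asserted
    relation type or ``none``, limited to a token-distance window."""
    doc = normalize_relations(doc)
    tokens = tokenize_text(doc.text)
    tok_of: dict[str, int] = {}
    for e in doc.entities:
        for i, t in enumerate(tokens):
            if min(t.end, e.span.end) - max(t.start, e.span.start) > 0:
                tok_of[e.id] = i
                break
    gold = {(r.arg1, r.arg2): r.rtype for r in doc.relations}
    out = []
    ents = sorted(doc.entities, key=lambda e: e.span.start)
    for i, a in enumerate(ents):
        for b in ents[i + 1 :]:
            if (
                max_token_distance is not None
                and abs(tok_of.get(a.id, 0) - tok_of.get(b.id, 0)) > max_token_distance
            ):
                continue
            for x, y in ((a.id, b.id), (b.id, a.id)):
                out.append(
                    RelationCandidate(doc.doc_id, x, y, gold.get((x, y), "none"))
                )
    return out


def write_candidates(corpus: AnnotatedCorpus, max_token_distance: Optional[int] = 50) -> str:
    lines = []
    for doc_id in corpus.doc_ids:
        doc = corpus.get(doc_id, corpus.annotators_of(doc_id)[0])
        for c in relation_candidates(doc, max_token_distance):
            lines.append(f"{c.doc_id}\t{c.arg1}\t{c.arg2}\t{c.label}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class EvaluationResult:
    accuracy: float
    f1: float
    precision: float
    recall: float
    counts: MatchCounts = field(default_factory=MatchCounts)


def evaluate_predictions(
    pred: AnnotatedCorpus,
    gold: AnnotatedCorpus,
    task: str = "ner",
    use_closure: bool = False,
) -> EvaluationResult:
    """Score predicted annotations against a gold corpus.

    NER is scored token-level over BIO tags: precision/recall/F1 over
    non-O tokens, accuracy over all tokens including O/O agreements.
    REX is scored over ordered entity pairs asserted by either side
    (matched via gold entity ids); with ``use_closure`` a predicted
    edge also counts when the gold closure entails it.
    """
    if set(pred.doc_ids) != set(gold.doc_ids):
        raise AnnotationError("prediction and gold corpora cover different documents")
    counts = MatchCounts()
    n_agree = 0  # scoring units (tokens / pairs) where both sides agree
    n_units = 0
    if task == "ner":
        for doc_id in gold.doc_ids:
            g = gold.get(doc_id, gold.annotators_of(doc_id)[0])
            p = pred.get(doc_id, pred.annotators_of(doc_id)[0])
            gt = to_bio(g).tags
            pt = to_bio(p).tags
            n_units += len(gt)
            for tg, tp in zip(gt, pt):
                if tg == tp:
                    n_agree += 1
                if tg == "O" and tp == "O":
                    counts = counts + MatchCounts(tn=1)
                elif tg == tp:
                    counts = counts + MatchCounts(tp=1)
                elif tp == "O":
                    counts = counts + MatchCounts(fn=1)
                elif tg == "O":
                    counts = counts + MatchCounts(fp=1)
                else:
                    counts = counts + MatchCounts(fp=1, fn=1)
    elif task == "rex":
        for doc_id in gold.doc_ids:
            g = normalize_relations(gold.get(doc_id, gold.annotators_of(doc_id)[0]))
            p = normalize_relations(pred.get(doc_id, pred.annotators_of(doc_id)[0]))
            gold_edges = g.relation_edges()
            check_edges = gold_edges
            if use_closure:
                check_edges = compute_closure(build_graph(g)).edges
            pred_edges = p.relation_edges()
            tp = len(pred_edges & check_edges)
            fn = len(gold_edges - pred_edges)
            counts = counts + MatchCounts(tp=tp, fp=len(pred_edges) - tp, fn=fn)
            # Accuracy over candidate pairs, counting mutual-none pairs.
            cands = relation_candidates(g)
            pred_by_pair = {(r.arg1, r.arg2): r.rtype for r in p.relations}
            gold_by_pair = {(r.arg1, r.arg2): r.rtype for r in g.relations}
            for c in cands:
                n_units += 1
                if pred_by_pair.get((c.arg1, c.arg2), "none") == gold_by_pair.get(
                    (c.arg1, c.arg2), "none"
                ):
                    n_agree += 1
    else:
        raise ValueError(f"unknown task {task!r}")
    prf = compute_prf(counts)
    acc = n_agree / n_units if n_units else 0.0
    return EvaluationResult(
        accuracy=acc, f1=prf.f1, precision=prf.precision, recall=prf.recall, counts=counts
    )


# ---------------------------------------------------------------------------
# Rule-based time-expression baseline

_DATE_RE = re.compile(
    r"\b\d{1,2}\.\d{1,2}\.\d{2,4}\b"   # 13.05.2019
    r"|\b\d{1,2}\.\d{4}\b"             # 06.2020
    r"|\b\d{1,2}\.?\s(?:Januar|Februar|März|April|Mai|Juni|Juli|August|September"
    r"|Oktober|November|Dezember)\s\d{4}\b"
)
_TIME_RE = re.compile(r"\b\d{1,2}:\d{2}\b")


def rule_timex_baseline(text: str, doc_id: str = "doc", annotator_id: str = "rulebase") -> DocumentAnnotation:
    """Tag day-month-year / month-year patterns as Date and clock
    patterns as Time. A deliberately minimal stand-in tagger that
    exercises the evaluation path end to end."""
    entities = []
    for m in _DATE_RE.finditer(text):
        entities.append(
            EntityAnnotation(
                id=f"T{len(entities) + 1}",
                label="Date",
                span=Span(m.start(), m.end()),
                surface=m.group(),
            )
        )
    for m in _TIME_RE.finditer(text):
        entities.append(
            EntityAnnotation(
                id=f"T{len(entities) + 1}",
                label="Time",
                span=Span(m.start(), m.end()),
                surface=m.group(),
            )
        )
    return DocumentAnnotation(
        doc_id=doc_id, annotator_id=annotator_id, text=text, entities=entities
    )


def run_baseline(gold: AnnotatedCorpus) -> AnnotatedCorpus:
    docs = []
    for doc_id in gold.doc_ids:
        g = gold.get(doc_id, gold.annotators_of(doc_id)[0])
        docs.append(rule_timex_baseline(g.text, doc_id=doc_id))
    return corpus_from_documents(docs)
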