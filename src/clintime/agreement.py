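"""Pairwise inter-annotator agreement for temporal annotations.

Entity agreement is mean pairwise precision/recall/F1 over all
annotator pairs on the agreement documents, at two granularities:
mention-exact (identical span and label) and token level (each token
carries each annotator's label, unannotated tokens count as agreeing
"None" in the overall score). Relation agreement is closure-aware: an
asserted edge counts as correct when the other annotator's temporal
closure entails it, so two annotators who sparsely annotated the same
underlying order agree perfectly even if they share few edges.

Confusion matrices carry an explicit "None" category for mentions or
edges present on only one side — missing annotations, not label
swaps, dominate disagreement in this kind of campaign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .closure import (
    InconsistentGraphError,
    TemporalGraph,
    build_graph,
    compute_closure,
    most_specific,
)
from .schema import (
    AnnotatedCorpus,
    AnnotationError,
    CORE_RELATION_TYPES,
    DocumentAnnotation,
    ENTITY_LABELS,
    EntityAnnotation,
    RelationAnnotation,
    Span,
    normalize_relations,
)
from .text import tokenize_text

logger = logging.getLogger(__name__)

NONE_LABEL = "None"


@dataclass(frozen=True)
class MatchCounts:
    """Contingency counts of one response-vs-reference comparison."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.precision, self.recall, self.f1))


def compute_prf(counts: MatchCounts) -> PRF:
    """P = tp/(tp+fp), R = tp/(tp+fn), F1 = harmonic mean.

    A zero denominator yields 0 for that metric and sets the
    ``degenerate`` flag.
    """
    degenerate = False
    if counts.tp + counts.fp > 0:
        p = counts.tp / (counts.tp + counts.fp)
    else:
        p, degenerate = 0.0, True
    if counts.tp + counts.fn > 0:
        r = counts.tp / (counts.tp + counts.fn)
    else:
        r, degenerate = 0.0, True
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return PRF(p, r, f1, degenerate)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def compute_accuracy(counts: MatchCounts) -> tuple[float, bool]:
    """Acc = (tp+tn)/(tp+tn+fp+fn); (0, True) on an empty comparison."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0:
        return 0.0, True
    return (counts.tp + counts.tn) / total, False


# ---------------------------------------------------------------------------
# Entity matching

@dataclass
class EntityAlignment:
    """Result of aligning two annotators' mentions on one document."""

    pairs: list[tuple[EntityAnnotation, EntityAnnotation]] = field(default_factory=list)
    unmatched_a: list[EntityAnnotation] = field(default_factory=list)
    unmatched_b: list[EntityAnnotation] = field(default_factory=list)


def _align_by_overlap(
    ents_a: Sequence[EntityAnnotation], ents_b: Sequence[EntityAnnotation]
) -> EntityAlignment:
    """Greedy 1:1 alignment by maximal character overlap; exact span
    matches are taken first, remaining ties break by leftmost start."""
    out = EntityAlignment()
    by_span_b: dict[tuple[int, int], list[EntityAnnotation]] = {}
    for e in ents_b:
        by_span_b.setdefault((e.span.start, e.span.end), []).append(e)
    used_b: set[str] = set()
    rest_a: list[EntityAnnotation] = []
    for ea in sorted(ents_a, key=lambda e: (e.span.start, e.span.end, e.id)):
        exact = [
            eb for eb in by_span_b.get((ea.span.start, ea.span.end), []) if eb.id not in used_b
        ]
        if exact:
            out.pairs.append((ea, exact[0]))
            used_b.add(exact[0].id)
        else:
            rest_a.append(ea)
    candidates = []
    for ea in rest_a:
        for eb in ents_b:
            if eb.id in used_b:
                continue
            ov = ea.span.overlap(eb.span)
            if ov > 0:
                candidates.append((-ov, ea.span.start, eb.span.start, ea.id, eb.id, ea, eb))
    used_a: set[str] = set()
    for _, _, _, _, _, ea, eb in sorted(candidates, key=lambda c: c[:5]):
        if ea.id in used_a or eb.id in used_b:
            continue
        out.pairs.append((ea, eb))
        used_a.add(ea.id)
        used_b.add(eb.id)
    out.unmatched_a = [e for e in rest_a if e.id not in used_a]
    out.unmatched_b = [e for e in ents_b if e.id not in used_b]
    return out


@dataclass
class TokenAlignment:
    """Per-token label pairs (label or None) for one document."""

    labels_a: list[Optional[str]]
    labels_b: list[Optional[str]]


def _token_labels(doc: DocumentAnnotation) -> list[Optional[str]]:
    tokens = tokenize_text(doc.text)
    labels: list[Optional[str]] = [None] * len(tokens)
    for e in sorted(doc.entities, key=lambda e: -len(e.span)):
        for i, t in enumerate(tokens):
            if min(t.end, e.span.end) - max(t.start, e.span.start) > 0:
                labels[i] = e.label
    return labels


def match_entities(
    a: DocumentAnnotation, b: DocumentAnnotation, mode: str = "mention"
) -> EntityAlignment | TokenAlignment:
    """Align two annotators' mentions on the same document.

    ``mention`` mode pairs mentions greedily by character overlap
    (exact span matches first); a pair *agrees* only when spans and
    labels are identical. ``token`` mode labels every token with each
    annotator's covering entity label (or None).
    """
    if a.doc_id != b.doc_id:
        raise AnnotationError(f"doc_id mismatch: {a.doc_id} vs {b.doc_id}")
    if mode == "mention":
        return _align_by_overlap(a.entities, b.entities)
    if mode == "token":
        return TokenAlignment(_token_labels(a), _token_labels(b))
    raise ValueError(f"unknown mode {mode!r}")


def _mention_counts(
    a: DocumentAnnotation, b: DocumentAnnotation
) -> dict[str, MatchCounts]:
    """Strict mention counts per label, a = response, b = reference.

    tp requires identical span *and* label; every response mention not
    a tp is an fp for its label, every reference mention not a tp an fn.
    """
    spans_b: dict[tuple[int, int, str], int] = {}
    for e in b.entities:
        key = (e.span.start, e.span.end, e.label)
        spans_b[key] = spans_b.get(key, 0) + 1
    counts: dict[str, MatchCounts] = {lab: MatchCounts() for lab in ENTITY_LABELS}
    matched_b: dict[tuple[int, int, str], int] = {}
    for e in a.entities:
        key = (e.span.start, e.span.end, e.label)
        if matched_b.get(key, 0) < spans_b.get(key, 0):
            matched_b[key] = matched_b.get(key, 0) + 1
            counts[e.label] = counts[e.label] + MatchCounts(tp=1)
        else:
            counts[e.label] = counts[e.label] + MatchCounts(fp=1)
    for (s, t, lab), n in spans_b.items():
        miss = n - matched_b.get((s, t, lab), 0)
        if miss > 0:
            counts[lab] = counts[lab] + MatchCounts(fn=miss)
    return counts


def _token_counts(a: DocumentAnnotation, b: DocumentAnnotation) -> dict[str, MatchCounts]:
    """Token-level counts per label plus the None pseudo-label
    (mutual-None tokens appear as its tp)."""
    ta = _token_labels(a)
    tb = _token_labels(b)
    labels = list(ENTITY_LABELS) + [NONE_LABEL]
    counts = {lab: MatchCounts() for lab in labels}
    for la, lb in zip(ta, tb):
        la_ = la if la is not None else NONE_LABEL
        lb_ = lb if lb is not None else NONE_LABEL
        if la_ == lb_:
            counts[la_] = counts[la_] + MatchCounts(tp=1)
        else:
            counts[la_] = counts[la_] + MatchCounts(fp=1)
            counts[lb_] = counts[lb_] + MatchCounts(fn=1)
    return counts


# ---------------------------------------------------------------------------
# Corpus-level agreement

@dataclass(frozen=True)
class LabelScore:
    """Mean +- SD over annotator pairs for one label (or overall)."""

    precision: float
    precision_sd: float
    recall: float
    recall_sd: float
    f1: float
    f1_sd: float
    n_pairs: int


@dataclass
class AgreementScore:
    mode: str
    per_label: dict[str, LabelScore]
    overall: LabelScore
    #: token mode only: overall restricted to annotated tokens.
    overall_annotated: Optional[LabelScore] = None
    #: documents skipped because an annotator's graph was inconsistent.
    n_excluded_docs: int = 0


def _aggregate(per_pair: dict[str, list[PRF]]) -> dict[str, LabelScore]:
    """Population mean/SD across annotator pairs per label; pairs where
    a label never occurred on either side are excluded for it."""
    out = {}
    for label, scores in per_pair.items():
        if not scores:
            continue
        p = np.array([s.precision for s in scores])
        r = np.array([s.recall for s in scores])
        f = np.array([s.f1 for s in scores])
        out[label] = LabelScore(
            float(p.mean()), float(p.std()),
            float(r.mean()), float(r.std()),
            float(f.mean()), float(f.std()),
            len(scores),
        )
    return out


def _symmetrize(ab: dict[str, MatchCounts], ba: dict[str, MatchCounts]) -> dict[str, PRF]:
    """Average both reference/response orientations per label."""
    out = {}
    for label in set(ab) | set(ba):
        c_ab = ab.get(label, MatchCounts())
        c_ba = ba.get(label, MatchCounts())
        if c_ab.tp + c_ab.fp + c_ab.fn + c_ba.tp + c_ba.fp + c_ba.fn == 0:
            continue
        s_ab = compute_prf(c_ab)
        s_ba = compute_prf(c_ba)
        p = (s_ab.precision + s_ba.precision) / 2
        r = (s_ab.recall + s_ba.recall) / 2
        out[label] = PRF(p, r, (s_ab.f1 + s_ba.f1) / 2)
    return out


def _agreement_pairs(corpus: AnnotatedCorpus) -> list[tuple[str, list[str]]]:
    docs = sorted(corpus.agreement_docs) if corpus.agreement_docs else corpus.doc_ids
    out = []
    for d in docs:
        annotators = corpus.annotators_of(d)
        if len(annotators) >= 2:
            out.append((d, annotators))
    if not out:
        raise AnnotationError("agreement requires >= 2 annotators on shared documents")
    return out


def entity_agreement(corpus: AnnotatedCorpus, mode: str = "mention") -> AgreementScore:
    """Mean pairwise entity P/R/F1 (+- SD) over annotator pairs.

    Per annotator pair, counts are pooled over all agreement documents,
    scored per label in both orientations and averaged. Token mode
    reports two overall variants: counting unannotated tokens as an
    agreeing None label (the headline "overall agreement") and
    restricted to annotated tokens.
    """
    doc_pairs = _agreement_pairs(corpus)
    annotators = sorted({a for _, anns in doc_pairs for a in anns})
    count_fn = _mention_counts if mode == "mention" else _token_counts
    if mode not in ("mention", "token"):
        raise ValueError(f"unknown mode {mode!r}")

    per_label_pairwise: dict[str, list[PRF]] = {lab: [] for lab in ENTITY_LABELS}
    overall_pairwise: list[PRF] = []
    overall_annotated_pairwise: list[PRF] = []

    for a1, a2 in combinations(annotators, 2):
        tot_ab: dict[str, MatchCounts] = {}
        tot_ba: dict[str, MatchCounts] = {}
        seen = False
        for d, anns in doc_pairs:
            if a1 not in anns or a2 not in anns:
                continue
            seen = True
            for label, c in count_fn(corpus.get(d, a1), corpus.get(d, a2)).items():
                tot_ab[label] = tot_ab.get(label, MatchCounts()) + c
            for label, c in count_fn(corpus.get(d, a2), corpus.get(d, a1)).items():
                tot_ba[label] = tot_ba.get(label, MatchCounts()) + c
        if not seen:
            continue
        sym = _symmetrize(tot_ab, tot_ba)
        for label in ENTITY_LABELS:
            if label in sym:
                per_label_pairwise[label].append(sym[label])
        # Overall: micro-pool over labels (None included in token mode).
        keys_all = [k for k in tot_ab if mode == "token" or k != NONE_LABEL]
        micro_ab = sum((tot_ab[k] for k in keys_all), MatchCounts())
        micro_ba = sum((tot_ba.get(k, MatchCounts()) for k in keys_all), MatchCounts())
        sym_overall = _symmetrize({"_": micro_ab}, {"_": micro_ba})
        if "_" in sym_overall:
            overall_pairwise.append(sym_overall["_"])
        if mode == "token":
            keys_ann = [k for k in tot_ab if k != NONE_LABEL]
            mi_ab = sum((tot_ab[k] for k in keys_ann), MatchCounts())
            mi_ba = sum((tot_ba.get(k, MatchCounts()) for k in keys_ann), MatchCounts())
            sym_ann = _symmetrize({"_": mi_ab}, {"_": mi_ba})
            if "_" in sym_ann:
                overall_annotated_pairwise.append(sym_ann["_"])

    empty = LabelScore(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    per_label = _aggregate(per_label_pairwise)
    overall = _aggregate({"_": overall_pairwise}).get("_", empty)
    overall_annotated = (
        _aggregate({"_": overall_annotated_pairwise}).get("_", empty)
        if mode == "token"
        else None
    )
    return AgreementScore(
        mode=mode, per_label=per_label, overall=overall, overall_annotated=overall_annotated
    )


# ---------------------------------------------------------------------------
# Confusion matrices

@dataclass
class ConfusionMatrix:
    """Counts of aligned label pairs, with a None row/column for
    mentions or edges present on one side only."""

    counts: pd.DataFrame  # index = first annotator's label, columns = second's

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def normalized(self, by: str = "all") -> pd.DataFrame:
        """Proportions: ``all`` divides by the grand total (1.0 = all
        pairs, as in heatmap figures), ``row`` normalizes each non-empty
        row to 1."""
        c = self.counts.astype(float)
        if by == "all":
            total = c.values.sum()
            return c / total if total else c
        if by == "row":
            sums = c.sum(axis=1)
            return c.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
        raise ValueError(f"unknown normalization {by!r}")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def entity_confusion(corpus: AnnotatedCorpus) -> ConfusionMatrix:
    """Label-pair counts over overlap-aligned mentions of every
    annotator pair; unmatched mentions land in the None row/column."""
    doc_pairs = _agreement_pairs(corpus)
    labels = list(ENTITY_LABELS) + [NONE_LABEL]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for d, anns in doc_pairs:
        for a1, a2 in combinations(anns, 2):
            al = _align_by_overlap(corpus.get(d, a1).entities, corpus.get(d, a2).entities)
            for ea, eb in al.pairs:
                mat.loc[ea.label, eb.label] += 1
            for ea in al.unmatched_a:
                mat.loc[ea.label, NONE_LABEL] += 1
            for eb in al.unmatched_b:
                mat.loc[NONE_LABEL, eb.label] += 1
    return ConfusionMatrix(counts=mat)


# ---------------------------------------------------------------------------
# Relation agreement (closure-aware)

def _entity_id_map(a: DocumentAnnotation, b: DocumentAnnotation) -> dict[str, str]:
    """Map a's entity ids to b's via span alignment (exact first)."""
    al = _align_by_overlap(a.entities, b.entities)
    return {ea.id: eb.id for ea, eb in al.pairs}


def _edge_in_closure(edge: tuple[str, str, str], closure_edges: set) -> bool:
    a, b, t = edge
    if (a, b, t) in closure_edges:
        return True
    if t == "OVERLAP" and (b, a, t) in closure_edges:
        return True  # OVERLAP constraints are symmetric; compare unordered
    return False


def _doc_closures(
    corpus: AnnotatedCorpus, doc_pairs
) -> tuple[dict[tuple[str, str], TemporalGraph], dict[tuple[str, str], TemporalGraph], set]:
    """Per (doc, annotator): asserted graph and closure; documents where
    any annotator's graph is inconsistent are excluded (logged)."""
    graphs: dict[tuple[str, str], TemporalGraph] = {}
    closures: dict[tuple[str, str], TemporalGraph] = {}
    bad_docs: set[str] = set()
    for d, anns in doc_pairs:
        for a in anns:
            doc = normalize_relations(corpus.get(d, a))
            g = build_graph(doc)
            try:
                closures[(d, a)] = compute_closure(g)
            except InconsistentGraphError as exc:
                logger.warning("document %s annotator %s inconsistent: %s", d, a, exc)
                bad_docs.add(d)
                continue
            graphs[(d, a)] = g
    return graphs, closures, bad_docs


def relation_agreement(corpus: AnnotatedCorpus) -> AgreementScore:
    """Closure-aware pairwise relation agreement.

    With annotator A as response and B as reference on one document,
    precision is the fraction of A's asserted edges entailed by B's
    closure; recall mirrors it with roles swapped. Entities are aligned
    across annotators by span; an edge touching an entity the other
    annotator did not mark can never be verified in their closure.
    Scores are symmetrized over both orientations, pooled per annotator
    pair over documents, and reported as mean +- SD across pairs.
    """
    doc_pairs = _agreement_pairs(corpus)
    graphs, closures, bad_docs = _doc_closures(corpus, doc_pairs)
    doc_pairs = [(d, anns) for d, anns in doc_pairs if d not in bad_docs]
    annotators = sorted({a for _, anns in doc_pairs for a in anns})
    types = list(CORE_RELATION_TYPES)

    per_label_pairwise: dict[str, list[PRF]] = {t: [] for t in types}
    overall_pairwise: list[PRF] = []

    def directed_counts(d: str, resp: str, ref: str) -> dict[str, MatchCounts]:
        """Counts with `resp` as response scored against closure(ref)."""
        idmap = _entity_id_map(corpus.get(d, resp), corpus.get(d, ref))
        ref_closure = closures[(d, ref)].edges
        counts = {t: MatchCounts() for t in types}
        for a1, a2, t in graphs[(d, resp)].edges:
            mapped = (idmap.get(a1), idmap.get(a2), t)
            ok = (
                mapped[0] is not None
                and mapped[1] is not None
                and _edge_in_closure(mapped, ref_closure)
            )
            counts[t] = counts[t] + (MatchCounts(tp=1) if ok else MatchCounts(fp=1))
        return counts

    for a1, a2 in combinations(annotators, 2):
        tot_ab: dict[str, MatchCounts] = {t: MatchCounts() for t in types}
        tot_ba: dict[str, MatchCounts] = {t: MatchCounts() for t in types}
        seen = False
        for d, anns in doc_pairs:
            if a1 not in anns or a2 not in anns:
                continue
            seen = True
            for t, c in directed_counts(d, a1, a2).items():
                tot_ab[t] = tot_ab[t] + c
            for t, c in directed_counts(d, a2, a1).items():
                tot_ba[t] = tot_ba[t] + c
        if not seen:
            continue

        def sym_score(c_ab: MatchCounts, c_ba: MatchCounts) -> Optional[PRF]:
            """One orientation's precision is the other's recall: with A
            as response, P = |R_A in closure(B)| / |R_A| and
            R = |R_B in closure(A)| / |R_B|; averaging both orientations
            makes precision, recall (and hence F1) coincide."""
            n_ab = c_ab.tp + c_ab.fp
            n_ba = c_ba.tp + c_ba.fp
            if n_ab + n_ba == 0:
                return None
            p1 = c_ab.tp / n_ab if n_ab else 0.0
            p2 = c_ba.tp / n_ba if n_ba else 0.0
            sym = (p1 + p2) / 2
            return PRF(sym, sym, f1_score(p1, p2))

        for t in types:
            s = sym_score(tot_ab[t], tot_ba[t])
            if s is not None:
                per_label_pairwise[t].append(s)
        micro = sym_score(
            sum((tot_ab[t] for t in types), MatchCounts()),
            sum((tot_ba[t] for t in types), MatchCounts()),
        )
        if micro is not None:
            overall_pairwise.append(micro)

    empty = LabelScore(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)
    return AgreementScore(
        mode="relation",
        per_label=_aggregate(per_label_pairwise),
        overall=_aggregate({"_": overall_pairwise}).get("_", empty),
        n_excluded_docs=len(bad_docs),
    )


def relation_confusion(corpus: AnnotatedCorpus) -> ConfusionMatrix:
    """Relation-type pair counts over entity pairs either annotator
    asserted; the other side contributes its most specific entailed
    type, or None when its closure entails nothing for the pair."""
    doc_pairs = _agreement_pairs(corpus)
    graphs, closures, bad_docs = _doc_closures(corpus, doc_pairs)
    doc_pairs = [(d, anns) for d, anns in doc_pairs if d not in bad_docs]
    labels = list(CORE_RELATION_TYPES) + [NONE_LABEL]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)

    for d, anns in doc_pairs:
        for a1, a2 in combinations(anns, 2):
            idmap = _entity_id_map(corpus.get(d, a1), corpus.get(d, a2))
            rev = {v: k for k, v in idmap.items()}
            # Everything below is keyed in a1's id space.
            asserted_a = {(x, y): t for x, y, t in graphs[(d, a1)].edges}
            asserted_b = {
                (rev[x], rev[y]): t
                for x, y, t in graphs[(d, a2)].edges
                if x in rev and y in rev
            }
            closure_a: dict[tuple[str, str], set[str]] = {}
            for x, y, t in closures[(d, a1)].edges:
                closure_a.setdefault((x, y), set()).add(t)
            closure_b: dict[tuple[str, str], set[str]] = {}
            for x, y, t in closures[(d, a2)].edges:
                if x in rev and y in rev:
                    closure_b.setdefault((rev[x], rev[y]), set()).add(t)
            unmapped_b = [
                t for x, y, t in graphs[(d, a2)].edges if x not in rev or y not in rev
            ]
            for pair in set(asserted_a) | set(asserted_b):
                la = asserted_a.get(pair) or most_specific(closure_a.get(pair, set()))
                lb = asserted_b.get(pair) or most_specific(closure_b.get(pair, set()))
                if la is None and lb is None:
                    continue
                mat.loc[la or NONE_LABEL, lb or NONE_LABEL] += 1
            for t in unmapped_b:
                mat.loc[NONE_LABEL, t] += 1
    return ConfusionMatrix(counts=mat)


# ---------------------------------------------------------------------------
# Merging annotation variants

@dataclass(frozen=True)
class Disagreement:
    kind: str  # label-disagreement | span-disagreement | doctime-disagreement | missing
    merged_id: str
    detail: str


def merge_annotations(
    variants: Sequence[DocumentAnnotation],
) -> tuple[DocumentAnnotation, list[Disagreement]]:
    """Unify annotation variants of one document.

    Mentions are grouped across annotators by span overlap; each group
    becomes one merged entity (majority span/label/doctime). Groups
    with conflicting labels, spans, or doctime tags, and groups missing
    from some annotators, are flagged. The merged output is valid
    standoff, intended as the input for a correction round.
    """
    if not variants:
        raise AnnotationError("no variants to merge")
    doc_id = variants[0].doc_id
    text = variants[0].text
    for v in variants[1:]:
        if v.doc_id != doc_id:
            raise AnnotationError("variants must share doc_id")
        if v.text != text:
            raise AnnotationError("variants must share the document text")

    # groups: list of dicts annotator -> entity
    groups: list[dict[str, EntityAnnotation]] = []
    for v in variants:
        taken: set[int] = set()
        for e in sorted(v.entities, key=lambda e: (e.span.start, e.span.end)):
            best, best_ov = None, 0
            for gi, g in enumerate(groups):
                if gi in taken or v.annotator_id in g:
                    continue
                ov = max(e.span.overlap(m.span) for m in g.values())
                if ov > best_ov:
                    best, best_ov = gi, ov
            if best is None:
                groups.append({v.annotator_id: e})
                taken.add(len(groups) - 1)
            else:
                groups[best][v.annotator_id] = e
                taken.add(best)

    def majority(values: Iterable) -> object:
        vals = [v for v in values if v is not None]
        if not vals:
            return None
        return max(sorted(set(vals), key=str), key=vals.count)

    all_annotators = [v.annotator_id for v in variants]
    merged_entities: list[EntityAnnotation] = []
    report: list[Disagreement] = []
    old_to_new: dict[tuple[str, str], str] = {}
    groups.sort(key=lambda g: min((e.span.start, e.span.end) for e in g.values()))
    for gi, g in enumerate(groups, 1):
        new_id = f"T{gi}"
        for ann, e in g.items():
            old_to_new[(ann, e.id)] = new_id
        spans = {(e.span.start, e.span.end) for e in g.values()}
        labels = {e.label for e in g.values()}
        doctimes = {e.doctime for e in g.values() if e.doctime is not None}
        span = majority([(e.span.start, e.span.end) for e in g.values()])
        label = majority([e.label for e in g.values()])
        doctime = majority([e.doctime for e in g.values()]) if label == "EVENT" else None
        start, end = span  # type: ignore[misc]
        merged_entities.append(
            EntityAnnotation(
                id=new_id,
                label=label,  # type: ignore[arg-type]
                span=Span(start, end),
                surface=text[start:end],
                doctime=doctime,  # type: ignore[arg-type]
            )
        )
        if len(labels) > 1:
            report.append(
                Disagreement("label-disagreement", new_id, "/".join(sorted(labels)))
            )
        if len(spans) > 1:
            report.append(Disagreement("span-disagreement", new_id, str(sorted(spans))))
        if len(doctimes) > 1:
            report.append(
                Disagreement("doctime-disagreement", new_id, "/".join(sorted(doctimes)))
            )
        missing = sorted(set(all_annotators) - set(g))
        if missing:
            report.append(
                Disagreement("missing", new_id, f"missing-for-{','.join(missing)}")
            )

    merged_rel_edges: set[tuple[str, str, str]] = set()
    merged_relations: list[RelationAnnotation] = []
    ri = 0
    for v in variants:
        for r in v.relations:
            na = old_to_new.get((v.annotator_id, r.arg1))
            nb = old_to_new.get((v.annotator_id, r.arg2))
            if na is None or nb is None or na == nb:
                continue
            if (na, nb, r.rtype) in merged_rel_edges:
                continue
            merged_rel_edges.add((na, nb, r.rtype))
            ri += 1
            merged_relations.append(
                RelationAnnotation(id=f"R{ri}", rtype=r.rtype, arg1=na, arg2=nb)
            )

    merged = DocumentAnnotation(
        doc_id=doc_id,
        annotator_id="merged",
        text=text,
        entities=merged_entities,
        relations=merged_relations,
    )
    return merged, report
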