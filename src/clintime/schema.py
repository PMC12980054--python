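"""Data model for TimeML-style temporal annotation of clinical documents.

The schema follows the THYME tradition: text-bound temporal entities
(EVENT plus the TIMEX3 subtypes), a document-time tag on every EVENT
describing its position relative to the reported hospital stay, and
typed directed temporal relations drawn from a five-type subset of
Allen's interval algebra (with AFTER kept only as surface syntax for
the inverse of BEFORE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

#: The closed vocabulary of entity labels. EVENT is the sole event-like
#: label; the remainder are the TIMEX3 family (DocTime marks the
#: document creation date line, annotated as an entity of its own).
ENTITY_LABELS = (
    "EVENT",
    "Date",
    "DocTime",
    "Time",
    "Duration",
    "Set",
    "Quantifier",
    "PrePost",
)

#: Document-time tags carried by EVENT entities: position of the event
#: relative to the reported hospital stay.
DOCTIME_TAGS = ("BEFORE", "BEFORE-OVERLAP", "OVERLAP", "AFTER")

#: Relation types as they may appear in standoff files. AFTER(Y, X) is
#: surface syntax for BEFORE(X, Y) and is removed by normalization.
RELATION_TYPES = ("BEFORE", "AFTER", "CONTAINS", "OVERLAP", "BEGINS-ON", "ENDS-ON")

#: Relation types after normalization (no AFTER).
CORE_RELATION_TYPES = ("BEFORE", "CONTAINS", "OVERLAP", "BEGINS-ON", "ENDS-ON")


class AnnotationError(ValueError):
    """Raised for malformed annotations or standoff content."""


@dataclass(frozen=True, order=True)
class Span:
    """Character span over the document text: 0-based, half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Span") -> int:
        """Number of characters shared with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class EntityAnnotation:
    """One text-bound temporal mention.

    ``doctime`` is present exactly when ``label == "EVENT"``.
    """

    id: str
    label: str
    span: Span
    surface: str
    doctime: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in ENTITY_LABELS:
            raise AnnotationError(f"unknown entity label {self.label!r}")
        if self.doctime is not None and self.doctime not in DOCTIME_TAGS:
            raise AnnotationError(f"unknown doctime tag {self.doctime!r}")


@dataclass(frozen=True)
class RelationAnnotation:
    """A typed, directed temporal edge between two entity ids.

    ``arg1`` plays the X role and ``arg2`` the Y role of the relation
    definitions (BEFORE(X, Y): X entirely before Y; CONTAINS(X, Y): Y
    entirely during X; ...).
    """

    id: str
    rtype: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if self.rtype not in RELATION_TYPES:
            raise AnnotationError(f"unknown relation type {self.rtype!r}")
        if self.arg1 == self.arg2:
            raise AnnotationError(f"self-relation on {self.arg1!r}")

    @property
    def edge(self) -> tuple[str, str, str]:
        """(arg1, arg2, rtype) triple, the identity of the assertion."""
        return (self.arg1, self.arg2, self.rtype)


@dataclass
class DocumentAnnotation:
    """All annotations of one annotator on one document."""

    doc_id: str
    annotator_id: str
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def entity_map(self) -> dict[str, EntityAnnotation]:
        return {e.id: e for e in self.entities}

    def relation_edges(self) -> set[tuple[str, str, str]]:
        return {r.edge for r in self.relations}


@dataclass(frozen=True)
class Violation:
    """One validation finding. ``fatal`` findings break round-tripping
    or graph construction; the rest are warnings."""

    kind: str
    message: str
    fatal: bool = True


def validate_document(doc: DocumentAnnotation) -> list[Violation]:
    """Check a document against the schema's invariants.

    Returns a (possibly empty) list of findings; never raises. Checked:
    EVENT without a document-time tag, a tag on a non-EVENT, spans out
    of text bounds, surface/text mismatches, self-relations, dangling
    relation arguments, duplicate entity ids, and Quantifier entities
    not paired with any EVENT (warning only).
    """
    out: list[Violation] = []
    seen_ids: set[str] = set()
    n = len(doc.text)
    for e in doc.entities:
        if e.id in seen_ids:
            out.append(Violation("duplicate-id", f"entity id {e.id} reused"))
        seen_ids.add(e.id)
        if e.span.end > n:
            out.append(
                Violation(
                    "span-out-of-bounds",
                    f"{e.id}: span [{e.span.start}, {e.span.end}) exceeds text length {n}",
                )
            )
        elif doc.text[e.span.start : e.span.end] != e.surface:
            out.append(
                Violation(
                    "surface-mismatch",
                    f"{e.id}: surface {e.surface!r} != text slice "
                    f"{doc.text[e.span.start:e.span.end]!r}",
                )
            )
        if e.label == "EVENT" and e.doctime is None:
            out.append(Violation("missing-doctime", f"EVENT {e.id} has no document-time tag"))
        if e.label != "EVENT" and e.doctime is not None:
            out.append(
                Violation(
                    "doctime-on-non-event",
                    f"{e.id} ({e.label}) carries doctime {e.doctime}",
                    fatal=False,
                )
            )
    emap = {e.id for e in doc.entities}
    related: set[str] = set()
    for r in doc.relations:
        for arg in (r.arg1, r.arg2):
            if arg not in emap:
                out.append(Violation("dangling-argument", f"{r.id}: unknown entity {arg}"))
            else:
                related.add(arg)
        if r.arg1 == r.arg2:
            out.append(Violation("self-relation", f"{r.id} relates {r.arg1} to itself"))
    by_id = doc.entity_map()
    for e in doc.entities:
        if e.label == "Quantifier":
            partners = {
                (by_id.get(r.arg2) if r.arg1 == e.id else by_id.get(r.arg1))
                for r in doc.relations
                if e.id in (r.arg1, r.arg2)
            }
            if not any(p is not None and p.label == "EVENT" for p in partners):
                out.append(
                    Violation(
                        "unpaired-quantifier",
                        f"Quantifier {e.id} has no relation to any EVENT",
                        fatal=False,
                    )
                )
    return out


def normalize_relations(doc: DocumentAnnotation) -> DocumentAnnotation:
    """Replace every AFTER(a, b) by the equivalent BEFORE(b, a).

    Idempotent. Duplicate assertions produced by the rewrite (or already
    present) are collapsed, keeping the first relation id.
    """
    seen: set[tuple[str, str, str]] = set()
    rels: list[RelationAnnotation] = []
    for r in doc.relations:
        if r.rtype == "AFTER":
            r = replace(r, rtype="BEFORE", arg1=r.arg2, arg2=r.arg1)
        if r.edge in seen:
            continue
        seen.add(r.edge)
        rels.append(r)
    return DocumentAnnotation(
        doc_id=doc.doc_id,
        annotator_id=doc.annotator_id,
        text=doc.text,
        entities=list(doc.entities),
        relations=rels,
    )


@dataclass
class AnnotatedCorpus:
    """Documents grouped by (doc_id, annotator_id).

    ``agreement_docs`` is the subset of doc_ids annotated by every
    annotator, on which inter-annotator agreement is computed.
    """

    documents: dict[tuple[str, str], DocumentAnnotation] = field(default_factory=dict)
    agreement_docs: set[str] = field(default_factory=set)

    def add(self, doc: DocumentAnnotation) -> None:
        self.documents[(doc.doc_id, doc.annotator_id)] = doc

    @property
    def doc_ids(self) -> list[str]:
        return sorted({d for d, _ in self.documents})

    @property
    def annotator_ids(self) -> list[str]:
        return sorted({a for _, a in self.documents})

    def annotators_of(self, doc_id: str) -> list[str]:
        return sorted(a for d, a in self.documents if d == doc_id)

    def get(self, doc_id: str, annotator_id: str) -> DocumentAnnotation:
        return self.documents[(doc_id, annotator_id)]

    def variants(self, doc_id: str) -> list[DocumentAnnotation]:
        return [self.documents[(doc_id, a)] for a in self.annotators_of(doc_id)]

    def normalized(self) -> "AnnotatedCorpus":
        out = AnnotatedCorpus(agreement_docs=set(self.agreement_docs))
        for doc in self.documents.values():
            out.add(normalize_relations(doc))
        return out


def corpus_from_documents(
    docs: Iterable[DocumentAnnotation], agreement_docs: Iterable[str] = ()
) -> AnnotatedCorpus:
    corpus = AnnotatedCorpus(agreement_docs=set(agreement_docs))
    for d in docs:
        corpus.add(d)
    return corpus
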