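"""Temporal graphs and interval-endpoint closure.

Annotators assert only a sparse, connected set of temporal relations
per document; two annotators may describe the same underlying order
through disjoint edge sets. Agreement is therefore computed against
the *closure*: the set of all relations logically entailed by the
asserted ones.

Each of the five relation types is translated into order constraints
on interval endpoints (strict semantics, reflecting the "entirely
before"/"entirely during" definitions):

==============  =============================================
BEFORE(X, Y)    end(X) < start(Y)
CONTAINS(X, Y)  start(X) < start(Y) and end(Y) < end(X)
OVERLAP(X, Y)   start(X) < end(Y) and start(Y) < end(X)
BEGINS-ON(X, Y) start(X) = start(Y)
ENDS-ON(X, Y)   end(X) = end(Y)
==============  =============================================

Constraints live in the point algebra over {<, =, >} without the
non-convex "not equal"; for this convex fragment, path-consistency
propagation (a Floyd-Warshall-style fixpoint over the composition
table) computes the minimal network, so entailment of a relation
reduces to a subset check on the propagated constraints. Closure then
emits, for every ordered vertex pair, every relation type whose
defining constraint set is entailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .schema import (
    AnnotationError,
    CORE_RELATION_TYPES,
    DocumentAnnotation,
    RelationAnnotation,
)

Edge = tuple[str, str, str]  # (arg1, arg2, rtype)

# Point-relation bitmasks.
LT, EQ, GT = 1, 2, 4
ALL = LT | EQ | GT

# Composition of the three base relations; unions extend bitwise.
_BASE_COMP = {
    (LT, LT): LT, (LT, EQ): LT, (LT, GT): ALL,
    (EQ, LT): LT, (EQ, EQ): EQ, (EQ, GT): GT,
    (GT, LT): ALL, (GT, EQ): GT, (GT, GT): GT,
}

COMP = np.zeros((8, 8), dtype=np.int8)
for a in range(8):
    for b in range(8):
        acc = 0
        for r1 in (LT, EQ, GT):
            if not a & r1:
                continue
            for r2 in (LT, EQ, GT):
                if b & r2:
                    acc |= _BASE_COMP[(r1, r2)]
        COMP[a, b] = acc

_CONVERSE = np.array([0, GT, EQ, EQ | GT, LT, LT | GT, LT | EQ, ALL], dtype=np.int8)


class InconsistentGraphError(AnnotationError):
    """The asserted relations admit no interval model."""

    def __init__(self, message: str, witness: Sequence[Edge] = ()):  # noqa: D107
        super().__init__(message)
        self.witness = list(witness)


@dataclass
class TemporalGraph:
    """Per-document temporal graph: entity ids as vertices, normalized
    relations (no AFTER) as directed typed edges."""

    vertices: list[str]
    edges: set[Edge] = field(default_factory=set)
    closed: bool = False

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        for a, b, t in self.edges:
            if t not in CORE_RELATION_TYPES:
                raise AnnotationError(f"unknown relation type {t!r} (normalize first?)")
            if a == b:
                raise AnnotationError(f"self-loop on {a!r}")
            if a not in vset or b not in vset:
                raise AnnotationError(f"edge ({a}, {b}, {t}) references unknown vertex")


def build_graph(doc: DocumentAnnotation) -> TemporalGraph:
    """Graph of a normalized document: all entities, all relations."""
    vertices = [e.id for e in doc.entities]
    vset = set(vertices)
    edges: set[Edge] = set()
    for r in doc.relations:
        if r.arg1 not in vset or r.arg2 not in vset:
            raise AnnotationError(f"relation {r.id} has dangling argument")
        edges.add(r.edge)
    return TemporalGraph(vertices=vertices, edges=edges)


def connected_components(graph: TemporalGraph) -> list[set[str]]:
    """Partition of the vertices ignoring edge direction and type.

    The annotation convention requires exactly one component per
    (non-empty) document, so a timeline of the whole stay exists.
    """
    parent = {v: v for v in graph.vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for v in graph.vertices:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda s: min(s))


# ---------------------------------------------------------------------------
# Point-constraint propagation

def _constraints_of(rtype: str) -> list[tuple[int, int, int]]:
    """Defining constraints as (point-of-X, point-of-Y, bitmask) with
    0 = start, 1 = end on each side."""
    if rtype == "BEFORE":
        return [(1, 0, LT)]
    if rtype == "CONTAINS":
        return [(0, 0, LT), (1, 1, GT)]  # start(X)<start(Y), end(X)>end(Y)
    if rtype == "OVERLAP":
        return [(0, 1, LT), (1, 0, GT)]  # start(X)<end(Y), end(X)>start(Y)
    if rtype == "BEGINS-ON":
        return [(0, 0, EQ)]
    if rtype == "ENDS-ON":
        return [(1, 1, EQ)]
    raise AnnotationError(f"unknown relation type {rtype!r}")


@dataclass
class PointConstraintMatrix:
    """Propagated endpoint constraints for one graph.

    Point ``2*i`` is the start and ``2*i + 1`` the end of interval
    ``vertices[i]``. ``matrix[p, q]`` is the bitmask of admitted order
    relations between points p and q; a zero cell marks a contradiction.
    """

    vertices: list[str]
    matrix: np.ndarray

    @property
    def consistent(self) -> bool:
        return bool((self.matrix != 0).all())

    def index(self, vertex: str) -> int:
        return self.vertices.index(vertex)


def propagate(graph: TemporalGraph, allow_instants: bool = False) -> PointConstraintMatrix:
    """Build the endpoint network and propagate to fixpoint.

    ``allow_instants`` relaxes the non-degeneracy constraint per
    interval from start < end to start <= end (point events).
    """
    vertices = list(graph.vertices)
    idx = {v: i for i, v in enumerate(vertices)}
    n = 2 * len(vertices)
    m = np.full((n, n), ALL, dtype=np.int8)
    np.fill_diagonal(m, EQ)
    nondegen = (LT | EQ) if allow_instants else LT
    for i in range(len(vertices)):
        m[2 * i, 2 * i + 1] &= nondegen
        m[2 * i + 1, 2 * i] &= _CONVERSE[nondegen]
    for a, b, t in graph.edges:
        ia, ib = idx[a], idx[b]
        for pa, pb, rel in _constraints_of(t):
            p, q = 2 * ia + pa, 2 * ib + pb
            m[p, q] &= rel
            m[q, p] &= _CONVERSE[rel]

    # Floyd-Warshall-style path consistency, repeated to fixpoint.
    while True:
        before = m.copy()
        for k in range(n):
            comp = COMP[m[:, k][:, None], m[k, :][None, :]]
            m &= comp
        if (m == before).all() or (m == 0).any():
            break
    return PointConstraintMatrix(vertices=vertices, matrix=m)


def check_consistency(
    graph: TemporalGraph, allow_instants: bool = False, minimize_witness: bool = True
) -> tuple[bool, list[Edge]]:
    """Whether the asserted relations admit an interval model.

    For inconsistent graphs, returns a small witness: an edge subset
    that already reproduces the contradiction (greedily minimized).
    """
    pcm = propagate(graph, allow_instants=allow_instants)
    if pcm.consistent:
        return True, []
    witness = sorted(graph.edges)
    if minimize_witness:
        kept = list(witness)
        for e in list(kept):
            trial = set(kept) - {e}
            sub = TemporalGraph(vertices=list(graph.vertices), edges=trial)
            if not propagate(sub, allow_instants=allow_instants).consistent:
                kept.remove(e)
        witness = sorted(kept)
    return False, witness


def entailed_relations(pcm: PointConstraintMatrix) -> set[Edge]:
    """All relations whose defining constraints are entailed by the
    minimal network — every type per ordered pair, not only the most
    specific one."""
    m = pcm.matrix
    nv = len(pcm.vertices)
    s = np.arange(nv) * 2
    e = s + 1
    ss = m[np.ix_(s, s)]
    ee = m[np.ix_(e, e)]
    es = m[np.ix_(e, s)]
    se = m[np.ix_(s, e)]
    out: set[Edge] = set()
    # CONTAINS(X, Y): start(X) < start(Y) and end(X) > end(Y)
    contains = (ss == LT) & (ee == GT)
    overlap = (se == LT) & (es == GT)
    begins = ss == EQ
    ends = ee == EQ
    names = pcm.vertices
    for i in range(nv):
        for j in range(nv):
            if i == j:
                continue
            if es[i, j] == LT:
                out.add((names[i], names[j], "BEFORE"))
            if contains[i, j]:
                out.add((names[i], names[j], "CONTAINS"))
            if overlap[i, j]:
                out.add((names[i], names[j], "OVERLAP"))
            if begins[i, j]:
                out.add((names[i], names[j], "BEGINS-ON"))
            if ends[i, j]:
                out.add((names[i], names[j], "ENDS-ON"))
    return out


def compute_closure(graph: TemporalGraph, allow_instants: bool = False) -> TemporalGraph:
    """Temporal closure: every relation entailed by the asserted set.

    Raises :class:`InconsistentGraphError` (with a minimal conflicting
    edge subset) if the input admits no interval model. The result is a
    superset of the input edges and is idempotent under re-closure.
    """
    pcm = propagate(graph, allow_instants=allow_instants)
    if not pcm.consistent:
        _, witness = check_consistency(graph, allow_instants=allow_instants)
        raise InconsistentGraphError(
            f"inconsistent temporal graph; conflicting edges: {witness}", witness
        )
    return TemporalGraph(
        vertices=list(graph.vertices), edges=entailed_relations(pcm), closed=True
    )


# Specificity order used when a single relation must represent a pair
# (confusion matrices): equal-endpoint and containment readings win
# over the weaker OVERLAP; BEFORE excludes all others anyway.
_SPECIFICITY = ("BEFORE", "BEGINS-ON", "ENDS-ON", "CONTAINS", "OVERLAP")


def most_specific(types: set[str]) -> Optional[str]:
    """Single most specific relation type among entailed ones."""
    for t in _SPECIFICITY:
        if t in types:
            return t
    return None


# ---------------------------------------------------------------------------
# Serialization of closures

def edge_list_rows(doc_id: str, graph: TemporalGraph, closure: TemporalGraph) -> list[tuple]:
    """Tab-separable rows (doc_id, arg1, arg2, rtype, asserted|inferred)."""
    rows = []
    for a, b, t in sorted(closure.edges):
        status = "asserted" if (a, b, t) in graph.edges else "inferred"
        rows.append((doc_id, a, b, t, status))
    return rows


def closed_document(doc: DocumentAnnotation, id_prefix: str = "RC") -> DocumentAnnotation:
    """Copy of ``doc`` with inferred edges appended as relations whose
    ids carry ``id_prefix``, so the closure can be written back to
    standoff and inspected in BRAT."""
    graph = build_graph(doc)
    closure = compute_closure(graph)
    asserted = graph.edges
    new_rels = list(doc.relations)
    counter = 0
    for a, b, t in sorted(closure.edges):
        if (a, b, t) in asserted:
            continue
        counter += 1
        new_rels.append(RelationAnnotation(id=f"{id_prefix}{counter}", rtype=t, arg1=a, arg2=b))
    return replace_relations(doc, new_rels)


def replace_relations(
    doc: DocumentAnnotation, relations: list[RelationAnnotation]
) -> DocumentAnnotation:
    return DocumentAnnotation(
        doc_id=doc.doc_id,
        annotator_id=doc.annotator_id,
        text=doc.text,
        entities=list(doc.entities),
        relations=relations,
    )
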