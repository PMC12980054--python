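"""Corpus statistics tables: entity and relation counts with
percentages, and the relation-surplus arithmetic.

Percentages are half-up rounded to 2 decimals, matching how such
tables are conventionally printed. Counts aggregate over one gold
variant per document (for agreement documents, a designated variant),
so multiply-annotated documents are not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .schema import (
    AnnotatedCorpus,
    CORE_RELATION_TYPES,
    DocumentAnnotation,
    ENTITY_LABELS,
    normalize_relations,
)


def percent(count: int, total: int) -> float:
    """100 * count / total, half-up rounded to 2 decimals."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def _gold_variants(corpus: AnnotatedCorpus, gold_annotator: Optional[str]) -> list[DocumentAnnotation]:
    """One variant per doc_id: the designated annotator's where present,
    otherwise the first annotator alphabetically."""
    out = []
    for d in corpus.doc_ids:
        annotators = corpus.annotators_of(d)
        if gold_annotator is not None and gold_annotator in annotators:
            out.append(corpus.get(d, gold_annotator))
        else:
            out.append(corpus.get(d, annotators[0]))
    return out


def entity_stats(
    corpus: AnnotatedCorpus, gold_annotator: Optional[str] = None
) -> pd.DataFrame:
    """One row per entity label in schema order plus a Total row, with
    absolute counts and 2-decimal percentages."""
    counts = {lab: 0 for lab in ENTITY_LABELS}
    for doc in _gold_variants(corpus, gold_annotator):
        for e in doc.entities:
            counts[e.label] += 1
    total = sum(counts.values())
    rows = [
        {"label": lab, "absolute": counts[lab], "percent": percent(counts[lab], total)}
        for lab in ENTITY_LABELS
    ]
    rows.append({"label": "Total", "absolute": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def relation_stats(
    corpus: AnnotatedCorpus, gold_annotator: Optional[str] = None
) -> pd.DataFrame:
    """One row per relation type (after AFTER normalization) plus Total."""
    counts = {t: 0 for t in CORE_RELATION_TYPES}
    for doc in _gold_variants(corpus, gold_annotator):
        for r in normalize_relations(doc).relations:
            counts[r.rtype] += 1
    total = sum(counts.values())
    rows = [
        {"label": t, "absolute": counts[t], "percent": percent(counts[t], total)}
        for t in CORE_RELATION_TYPES
    ]
    rows.append({"label": "Total", "absolute": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelationSurplus:
    """How many more relations than strictly necessary were annotated.

    Two conventions are reported. ``vs_entities`` compares the relation
    total with the entity total (negative values mean relations are
    "missing" relative to entities). ``spanning_minimum`` is the true
    connectivity minimum, entities - documents (a spanning tree needs
    n - 1 edges per document), and ``vs_spanning`` the surplus over it.
    ``per_doc_deficit`` is the mean shortfall per document under the
    first convention.
    """

    relations_total: int
    entities_total: int
    documents_total: int
    vs_entities: int
    spanning_minimum: int
    vs_spanning: int
    per_doc_deficit: float


def relation_surplus(
    corpus: AnnotatedCorpus, gold_annotator: Optional[str] = None
) -> RelationSurplus:
    docs = _gold_variants(corpus, gold_annotator)
    n_docs = len(docs)
    n_ents = sum(len(d.entities) for d in docs)
    n_rels = sum(len(normalize_relations(d).relations) for d in docs)
    return surplus_from_totals(n_rels, n_ents, n_docs)


def surplus_from_totals(n_relations: int, n_entities: int, n_documents: int) -> RelationSurplus:
    """Surplus arithmetic from already-aggregated totals (usable with
    externally printed table totals as well as with a corpus)."""
    vs_entities = n_relations - n_entities
    spanning_minimum = max(0, n_entities - n_documents)
    deficit = (-vs_entities / n_documents) if n_documents else 0.0
    return RelationSurplus(
        relations_total=n_relations,
        entities_total=n_entities,
        documents_total=n_documents,
        vs_entities=vs_entities,
        spanning_minimum=spanning_minimum,
        vs_spanning=n_relations - spanning_minimum,
        per_doc_deficit=deficit,
    )


def validate_stat_table(table: pd.DataFrame) -> list[str]:
    """Cross-check a stats table (own or external): percentages must
    re-derive from the absolute column and the Total row must equal the
    per-label sum. Returns human-readable inconsistency findings."""
    findings = []
    body = table[table["label"] != "Total"]
    total_rows = table[table["label"] == "Total"]
    total = int(total_rows["absolute"].iloc[0]) if len(total_rows) else int(body["absolute"].sum())
    if len(total_rows) and body["absolute"].sum() != total:
        findings.append(
            f"label counts sum to {int(body['absolute'].sum())}, Total row says {total}"
        )
    for _, row in body.iterrows():
        expect = percent(int(row["absolute"]), total)
        if abs(expect - float(row["percent"])) > 0.005:
            findings.append(
                f"{row['label']}: printed {row['percent']}% but {int(row['absolute'])}/{total} "
                f"= {expect}%"
            )
    s = float(body["percent"].sum())
    if abs(s - 100.0) > 0.05 and total > 0:
        findings.append(f"percentages sum to {s}, not 100")
    return findings


def format_table(table: pd.DataFrame) -> str:
    """Human-readable rendering with thousands separators."""
    lines = ["label\tabsolute\tpercent"]
    for _, row in table.iterrows():
        lines.append(f"{row['label']}\t{int(row['absolute']):,}\t{row['percent']:.2f}")
    return "\n".join(lines) + "\n"
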