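"""Metrics, entity/relation agreement, confusion matrices, merging."""

import numpy as np
import pytest

from clintime.agreement import (
    EntityAlignment,
    MatchCounts,
    compute_accuracy,
    compute_prf,
    entity_agreement,
    entity_confusion,
    f1_score,
    match_entities,
    merge_annotations,
    relation_agreement,
    relation_confusion,
)
from clintime.schema import (
    AnnotatedCorpus,
    AnnotationError,
    DocumentAnnotation,
    EntityAnnotation,
    RelationAnnotation,
    Span,
    corpus_from_documents,
)


def make_doc(annotator, entities, relations=(), text="since 2017 the finding persisted"):
    ents = []
    for i, (label, s, e) in enumerate(entities):
        doctime = "BEFORE" if label == "EVENT" else None
        ents.append(
            EntityAnnotation(f"T{i + 1}", label, Span(s, e), text[s:e], doctime=doctime)
        )
    rels = [RelationAnnotation(f"R{i + 1}", t, a, b) for i, (a, b, t) in enumerate(relations)]
    return DocumentAnnotation("d1", annotator, text, entities=ents, relations=rels)


def pair_corpus(doc_a, doc_b):
    return corpus_from_documents([doc_a, doc_b], agreement_docs={"d1"})


class TestMetrics:
    def test_perfect_counts(self):
        assert tuple(compute_prf(MatchCounts(tp=5))) == (1.0, 1.0, 1.0)

    def test_f1_matches_printed_table_rows(self):
        # harmonic means as printed in two-decimal metric tables
        assert round(f1_score(0.73, 0.84), 2) == 0.78
        assert round(f1_score(0.84, 0.87), 2) == 0.85

    def test_empty_comparison_is_degenerate_zero(self):
        prf = compute_prf(MatchCounts())
        assert tuple(prf) == (0.0, 0.0, 0.0) and prf.degenerate

    def test_accuracy(self):
        assert compute_accuracy(MatchCounts(tp=50, tn=50)) == (1.0, False)
        acc, flag = compute_accuracy(MatchCounts(tp=30, tn=60, fp=5, fn=5))
        assert acc == pytest.approx(0.90) and not flag
        assert compute_accuracy(MatchCounts()) == (0.0, True)


class TestMatchEntities:
    def test_identical_sets_fully_matched(self):
        a = make_doc("a", [("Date", 6, 10), ("EVENT", 15, 22)])
        b = make_doc("b", [("Date", 6, 10), ("EVENT", 15, 22)])
        al = match_entities(a, b)
        assert isinstance(al, EntityAlignment)
        assert len(al.pairs) == 2 and not al.unmatched_a and not al.unmatched_b

    def test_partial_overlap_aligned_with_label_conflict(self):
        # {since 2017} as Duration vs since {2017} as Date
        a = make_doc("a", [("Date", 6, 10)])
        b = make_doc("b", [("Duration", 0, 10)])
        al = match_entities(a, b)
        assert len(al.pairs) == 1
        ea, eb = al.pairs[0]
        assert (ea.label, eb.label) == ("Date", "Duration")

    def test_unmatched_entity_is_reported(self):
        a = make_doc("a", [("EVENT", 15, 22)])
        b = make_doc("b", [])
        al = match_entities(a, b)
        assert not al.pairs and len(al.unmatched_a) == 1

    def test_doc_id_mismatch_rejected(self):
        a = make_doc("a", [])
        b = make_doc("b", [])
        b.doc_id = "other"
        with pytest.raises(AnnotationError):
            match_entities(a, b)


class TestEntityAgreement:
    def test_identical_annotators_score_one(self, clean_pair_corpus):
        score = entity_agreement(clean_pair_corpus)
        assert score.overall.f1 == 1.0 and score.overall.f1_sd == 0.0
        for s in score.per_label.values():
            assert s.f1 == 1.0

    def test_hand_enumerated_two_annotator_case(self):
        a = make_doc("a", [("Date", 0, 4), ("EVENT", 15, 22)], text="x" * 30)
        b = make_doc("b", [("Date", 0, 4)], text="x" * 30)
        score = entity_agreement(pair_corpus(a, b))
        assert score.per_label["Date"].f1 == 1.0
        assert score.per_label["EVENT"].f1 == 0.0
        # overall micro: tp=1, one fp/fn depending on orientation
        assert score.overall.precision == pytest.approx((0.5 + 1.0) / 2)

    def test_three_annotators_average_of_pairwise(self):
        text = "x" * 30
        a = make_doc("a", [("Date", 0, 4), ("Set", 6, 9)], text=text)
        b = make_doc("b", [("Date", 0, 4), ("Set", 6, 9)], text=text)
        c = make_doc("c", [("Date", 0, 4)], text=text)
        corpus = corpus_from_documents([a, b, c], agreement_docs={"d1"})
        score = entity_agreement(corpus)
        # pairwise Set F1: (a,b)=1, (a,c) and (b,c) degenerate-0 on c's side:
        # orientation symmetrization gives (0+0)/2 = 0 for those pairs
        f_ab, f_ac, f_bc = 1.0, 0.0, 0.0
        assert score.per_label["Set"].f1 == pytest.approx(np.mean([f_ab, f_ac, f_bc]))
        assert score.per_label["Date"].f1 == 1.0

    def test_token_mode_counts_unannotated_tokens(self):
        text = "alpha beta gamma delta"
        a = make_doc("a", [("Date", 0, 5)], text=text)
        b = make_doc("b", [("Date", 0, 5)], text=text)
        score = entity_agreement(pair_corpus(a, b), mode="token")
        assert score.overall.f1 == 1.0  # includes 3 mutual-None tokens
        assert score.overall_annotated.f1 == 1.0

    def test_requires_two_annotators(self):
        a = make_doc("a", [])
        with pytest.raises(AnnotationError):
            entity_agreement(corpus_from_documents([a]))


class TestEntityConfusion:
    def test_identical_annotators_diagonal(self, clean_pair_corpus):
        conf = entity_confusion(clean_pair_corpus)
        off = conf.counts.values.sum() - np.trace(conf.counts.values)
        assert off == 0 and conf.counts.values.sum() > 0

    def test_missing_event_goes_to_none_cell(self):
        a = make_doc("a", [("EVENT", 15, 22)])
        b = make_doc("b", [])
        conf = entity_confusion(pair_corpus(a, b))
        assert conf.counts.loc["EVENT", "None"] == 1

    def test_row_normalization_sums_to_one(self):
        a = make_doc("a", [("Date", 6, 10), ("EVENT", 15, 22)])
        b = make_doc("b", [("Duration", 6, 10)])
        norm = entity_confusion(pair_corpus(a, b)).normalized(by="row")
        sums = norm.sum(axis=1)
        for v in sums:
            assert v == pytest.approx(1.0) or v == 0.0


def rel_doc(annotator, relations, n=3, text="x" * 30):
    ents = [("Date", 5 * i, 5 * i + 4) for i in range(n)]
    return make_doc(annotator, ents, relations, text=text)


class TestRelationAgreement:
    def test_identical_relation_sets_score_one(self, clean_pair_corpus):
        score = relation_agreement(clean_pair_corpus)
        assert score.overall.f1 == 1.0
        for s in score.per_label.values():
            assert s.f1 == 1.0

    def test_closure_aware_three_vertex_case(self):
        # A asserts a chain, B a fan-out from the first entity.
        a = rel_doc("a", [("T1", "T2", "BEFORE"), ("T2", "T3", "BEFORE")])
        b = rel_doc("b", [("T1", "T2", "BEFORE"), ("T1", "T3", "BEFORE")])
        score = relation_agreement(pair_corpus(a, b))
        # A as response: BEFORE(T2,T3) not entailed by closure(B): p1 = 1/2.
        # B as response: both edges entailed by closure(A): p2 = 1.
        assert score.overall.precision == pytest.approx(0.75)
        assert score.overall.f1 == pytest.approx(f1_score(0.5, 1.0))

    def test_different_spanning_sets_of_same_order_agree_fully(self):
        # Both annotators entail the same total order of three dates.
        a = rel_doc("a", [("T1", "T2", "BEFORE"), ("T2", "T3", "BEFORE")])
        b = rel_doc(
            "b",
            [("T1", "T2", "BEFORE"), ("T2", "T3", "BEFORE"), ("T1", "T3", "BEFORE")],
        )
        score = relation_agreement(pair_corpus(a, b))
        assert score.overall.f1 == 1.0

    def test_inconsistent_annotator_document_excluded(self):
        text = "y" * 30
        a = rel_doc("a", [("T1", "T2", "BEFORE"), ("T2", "T1", "BEFORE")], text=text)
        b = rel_doc("b", [("T1", "T2", "BEFORE")], text=text)
        ok_a = rel_doc("a", [("T1", "T2", "BEFORE")], text=text)
        ok_b = rel_doc("b", [("T1", "T2", "BEFORE")], text=text)
        ok_a.doc_id = ok_b.doc_id = "d2"
        corpus = corpus_from_documents([a, b, ok_a, ok_b], agreement_docs={"d1", "d2"})
        score = relation_agreement(corpus)
        assert score.n_excluded_docs == 1
        assert score.overall.f1 == 1.0  # only the consistent document scores


class TestRelationConfusion:
    def test_identical_diagonal(self, clean_pair_corpus):
        conf = relation_confusion(clean_pair_corpus)
        off = conf.counts.values.sum() - np.trace(conf.counts.values)
        assert off == 0 and conf.counts.values.sum() > 0

    def test_contains_vs_overlap_mass(self):
        a = rel_doc("a", [("T1", "T2", "CONTAINS"), ("T2", "T3", "BEFORE")])
        b = rel_doc("b", [("T1", "T2", "OVERLAP"), ("T2", "T3", "BEFORE")])
        conf = relation_confusion(pair_corpus(a, b))
        assert conf.counts.loc["CONTAINS", "OVERLAP"] == 1

    def test_unmatched_edge_contributes_none_cell(self):
        a = rel_doc("a", [("T1", "T2", "CONTAINS"), ("T2", "T3", "BEFORE")])
        b = rel_doc("b", [("T2", "T3", "BEFORE")])
        conf = relation_confusion(pair_corpus(a, b))
        assert conf.counts.loc["CONTAINS", "None"] == 1


class TestMerge:
    def test_identical_variants_merge_to_input(self):
        a = make_doc("a", [("Date", 6, 10), ("EVENT", 15, 22)])
        b = make_doc("b", [("Date", 6, 10), ("EVENT", 15, 22)])
        merged, report = merge_annotations([a, b])
        assert len(merged.entities) == 2 and report == []

    def test_label_conflict_flagged(self):
        a = make_doc("a", [("Date", 6, 10)])
        b = make_doc("b", [("Duration", 0, 10)])
        merged, report = merge_annotations([a, b])
        assert len(merged.entities) == 1
        kinds = {r.kind for r in report}
        assert "label-disagreement" in kinds and "span-disagreement" in kinds

    def test_minority_entity_flagged_missing(self):
        docs = [make_doc(x, [("Date", 6, 10)]) for x in "abcd"]
        docs[0] = make_doc("a", [("Date", 6, 10), ("EVENT", 15, 22)])
        merged, report = merge_annotations(docs)
        missing = [r for r in report if r.kind == "missing"]
        assert len(missing) == 1 and "missing-for-b,c,d" in missing[0].detail

    def test_text_mismatch_rejected(self):
        a = make_doc("a", [])
        b = make_doc("b", [], text="different text entirely here")
        with pytest.raises(AnnotationError):
            merge_annotations([a, b])
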