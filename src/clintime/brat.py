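"""Reading and writing BRAT standoff annotation (v1.3 subset).

Supported line types: text-bound entities (``T``), attributes (``A``,
carrying the EVENT document-time tag), and binary relations (``R``).
BRAT events (``E``), normalizations (``N``), notes (``#``) and
discontinuous span fragments are outside the schema and rejected or
reported. Offsets are 0-based half-open character offsets over the
decoded (UTF-8) text, as in BRAT itself.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

from .schema import (
    AnnotatedCorpus,
    AnnotationError,
    DocumentAnnotation,
    EntityAnnotation,
    RelationAnnotation,
    Span,
)

logger = logging.getLogger(__name__)

#: Standoff attribute name for the EVENT document-time tag. The value
#: is configurable on parse/write because annotation projects name this
#: attribute differently.
DEFAULT_DOCTIME_ATTRIBUTE = "DocTimeRel"


class BratParseError(AnnotationError):
    """Malformed standoff content; the message names the offending line."""


def parse_brat_document(
    text_content: str,
    standoff_content: str,
    doc_id: str,
    annotator_id: str = "",
    doctime_attribute: str = DEFAULT_DOCTIME_ATTRIBUTE,
) -> DocumentAnnotation:
    """Parse one ``.txt``/``.ann`` pair into a :class:`DocumentAnnotation`.

    Raises :class:`BratParseError` for dangling references, spans outside
    the text, or discontinuous spans. Unknown line types are logged as
    warnings, never silently dropped.
    """
    entities: dict[str, EntityAnnotation] = {}
    relations: list[RelationAnnotation] = []
    attributes: list[tuple[str, str, str, str]] = []  # (aid, name, target, value)

    for raw in standoff_content.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise BratParseError(f"malformed T line: {line!r}")
            header = fields[1]
            surface = fields[2] if len(fields) > 2 else ""
            if ";" in header:
                raise BratParseError(f"discontinuous spans are not supported: {line!r}")
            try:
                label, start_s, end_s = header.split(" ")
                span = Span(int(start_s), int(end_s))
            except (ValueError, AnnotationError) as exc:
                raise BratParseError(f"malformed T line {line!r}: {exc}") from exc
            if span.end > len(text_content):
                raise BratParseError(
                    f"{tag}: span [{span.start}, {span.end}) outside text "
                    f"of length {len(text_content)}"
                )
            entities[tag] = EntityAnnotation(
                id=tag, label=label, span=span, surface=text_content[span.start : span.end]
            )
            if surface and surface != entities[tag].surface:
                logger.warning(
                    "%s %s: standoff surface %r differs from text slice %r",
                    doc_id, tag, surface, entities[tag].surface,
                )
        elif tag.startswith("A"):
            if len(fields) < 2:
                raise BratParseError(f"malformed A line: {line!r}")
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise BratParseError(f"malformed A line (need name target value): {line!r}")
            attributes.append((tag, parts[0], parts[1], parts[2]))
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise BratParseError(f"malformed R line: {line!r}")
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise BratParseError(f"malformed R line: {line!r}")
            rtype = parts[0]
            args = {}
            for p in parts[1:]:
                k, _, v = p.partition(":")
                args[k] = v
            if set(args) != {"Arg1", "Arg2"}:
                raise BratParseError(f"R line needs Arg1 and Arg2: {line!r}")
            relations.append(
                RelationAnnotation(id=tag, rtype=rtype, arg1=args["Arg1"], arg2=args["Arg2"])
            )
        else:
            logger.warning("%s: unsupported standoff line type %r skipped", doc_id, line)

    for aid, name, target, value in attributes:
        if target not in entities:
            raise BratParseError(f"{aid}: attribute references undefined entity {target}")
        if name != doctime_attribute:
            logger.warning("%s %s: unknown attribute %r ignored", doc_id, aid, name)
            continue
        ent = entities[target]
        if ent.label != "EVENT":
            logger.warning(
                "%s %s: document-time tag on non-EVENT %s (%s)", doc_id, aid, target, ent.label
            )
        entities[target] = EntityAnnotation(
            id=ent.id, label=ent.label, span=ent.span, surface=ent.surface, doctime=value
        )

    for r in relations:
        for arg in (r.arg1, r.arg2):
            if arg not in entities:
                raise BratParseError(f"{r.id}: relation references undefined entity {arg}")

    return DocumentAnnotation(
        doc_id=doc_id,
        annotator_id=annotator_id,
        text=text_content,
        entities=list(entities.values()),
        relations=relations,
    )


def write_brat_document(
    doc: DocumentAnnotation,
    doctime_attribute: str = DEFAULT_DOCTIME_ATTRIBUTE,
) -> tuple[str, str]:
    """Serialize to a ``(text_content, standoff_content)`` pair.

    Inverse of :func:`parse_brat_document` on valid documents: parsing
    the output reproduces the document field for field.
    """
    lines: list[str] = []
    attr_no = 0
    for e in doc.entities:
        # newlines/tabs cannot appear inside a standoff line; the text
        # file stays authoritative for the true surface
        surface = e.surface.replace("\n", " ").replace("\t", " ")
        lines.append(f"{e.id}\t{e.label} {e.span.start} {e.span.end}\t{surface}")
        if e.doctime is not None:
            attr_no += 1
            lines.append(f"A{attr_no}\t{doctime_attribute} {e.id} {e.doctime}")
    for r in doc.relations:
        lines.append(f"{r.id}\t{r.rtype} Arg1:{r.arg1} Arg2:{r.arg2}")
    standoff = "\n".join(lines)
    if lines:
        standoff += "\n"
    return doc.text, standoff


# ---------------------------------------------------------------------------
# Corpus directory layout: one directory per annotator containing
# mirrored <doc_id>.txt / <doc_id>.ann pairs; alternatively a manifest
# (tab-separated: doc_id, annotator_id, path-stem).

def write_corpus(corpus: AnnotatedCorpus, root: str | Path) -> None:
    root = Path(root)
    for (doc_id, annotator_id), doc in sorted(corpus.documents.items()):
        adir = root / annotator_id
        adir.mkdir(parents=True, exist_ok=True)
        text, ann = write_brat_document(doc)
        (adir / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        (adir / f"{doc_id}.ann").write_text(ann, encoding="utf-8")
    if corpus.agreement_docs:
        (root / "agreement_docs.txt").write_text(
            "\n".join(sorted(corpus.agreement_docs)) + "\n", encoding="utf-8"
        )


def read_corpus(
    root: str | Path,
    annotators: Optional[Iterable[str]] = None,
    doctime_attribute: str = DEFAULT_DOCTIME_ATTRIBUTE,
) -> AnnotatedCorpus:
    """Read a per-annotator directory layout written by :func:`write_corpus`."""
    root = Path(root)
    corpus = AnnotatedCorpus()
    ann_dirs = (
        [root / a for a in annotators]
        if annotators is not None
        else sorted(p for p in root.iterdir() if p.is_dir())
    )
    for adir in ann_dirs:
        for txt in sorted(adir.glob("*.txt")):
            ann = txt.with_suffix(".ann")
            standoff = ann.read_text(encoding="utf-8") if ann.exists() else ""
            corpus.add(
                parse_brat_document(
                    txt.read_text(encoding="utf-8"),
                    standoff,
                    doc_id=txt.stem,
                    annotator_id=adir.name,
                    doctime_attribute=doctime_attribute,
                )
            )
    marker = root / "agreement_docs.txt"
    if marker.exists():
        corpus.agreement_docs = {
            line.strip() for line in marker.read_text(encoding="utf-8").splitlines() if line.strip()
        }
    else:
        n_annot = len(corpus.annotator_ids)
        corpus.agreement_docs = {
            d for d in corpus.doc_ids if len(corpus.annotators_of(d)) == n_annot > 1
        }
    return corpus


def read_manifest(
    manifest_path: str | Path, doctime_attribute: str = DEFAULT_DOCTIME_ATTRIBUTE
) -> AnnotatedCorpus:
    """Read a tab-separated manifest: ``doc_id  annotator_id  path-stem``.

    ``path-stem`` names the common stem of the ``.txt``/``.ann`` pair,
    relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    corpus = AnnotatedCorpus()
    for ln, line in enumerate(manifest_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise BratParseError(f"manifest line {ln}: need doc_id, annotator_id, path")
        doc_id, annotator_id, stem = parts
        txt = (base / stem).with_suffix(".txt")
        ann = (base / stem).with_suffix(".ann")
        corpus.add(
            parse_brat_document(
                txt.read_text(encoding="utf-8"),
                ann.read_text(encoding="utf-8") if ann.exists() else "",
                doc_id=doc_id,
                annotator_id=annotator_id,
                doctime_attribute=doctime_attribute,
            )
        )
    return corpus
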