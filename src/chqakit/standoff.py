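"""brat standoff reading and writing.

Documents live as ``<doc_id>.txt`` / ``<doc_id>.ann`` pairs; each annotator
has their own subdirectory.  Only term (T), event (E) and attribute (A)
lines are used: entities and question triggers are terms, frames are
events, and the topic flag, frame attributes and question-level exclusion
labels are attributes.  Whether a term is an entity or a trigger is decided
by scheme membership, so a file from the wrong scheme fails loudly instead
of parsing into nonsense.

brat has no document-level attributes, so question-level labels
(NOT_QUESTION, NOT_ANSWERABLE, DUPLICATE) are carried on a sentinel term
with the reserved label ``QUESTION`` spanning the document; the convention
round-trips through this module.

Offsets are 0-based, end-exclusive Unicode code points.  Text is read and
written as UTF-8 with newlines left untouched — offsets must match the
source bytes-for-characters.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

from .model import (
    EXCLUSION_LABELS,
    AnnotatedCorpus,
    EntityAnn,
    FrameAnn,
    Mention,
    QuestionDoc,
    Span,
    TriggerAnn,
)
from .schema import SchemeDefinition, load_scheme

__all__ = [
    "StandoffParseError",
    "parse_standoff",
    "write_standoff",
    "load_corpus",
    "save_corpus",
]

logger = logging.getLogger(__name__)

#: Reserved term label anchoring question-level attribute lines.
SENTINEL_LABEL = "QUESTION"

#: Attribute names accepted for the topic flag on read ("Focus" appears in
#: rendered form); written back as "Topic".
TOPIC_ALIASES = frozenset({"TOPIC", "FOCUS"})

_ROLE_SUFFIX = re.compile(r"^(.*?)(\d+)$")


class StandoffParseError(ValueError):
    """Malformed standoff input, carrying the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


def _strip_role_index(role: str) -> str:
    """brat numbers repeated roles (Theme2, Theme3); normalize them away."""
    m = _ROLE_SUFFIX.match(role)
    return m.group(1) if m else role


def _parse_spans(spec: str, line_no: int, text_len: int) -> tuple[Span, ...]:
    spans = []
    for frag in spec.split(";"):
        parts = frag.split()
        if len(parts) != 2:
            raise StandoffParseError(f"bad span fragment {frag!r}", line_no)
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise StandoffParseError(f"non-integer offsets in {frag!r}", line_no) from exc
        if not (0 <= start < end <= text_len):
            raise StandoffParseError(
                f"span ({start}, {end}) outside document of length {text_len}", line_no
            )
        spans.append(Span(start, end))
    out = tuple(sorted(spans))
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise StandoffParseError("overlapping span fragments", line_no)
    return out


def parse_standoff(
    text: str, ann: str, scheme: SchemeDefinition | str, doc_id: str = "doc"
) -> QuestionDoc:
    """Parse one document's annotation string against its text.

    Term labels are resolved case-insensitively against the scheme's entity
    and question-type inventories; a label in neither raises (corpora from
    different schemes must not silently mix).  Mention text recorded on T
    lines is cross-checked against the document offsets.
    """
    if isinstance(scheme, str):
        scheme = load_scheme(scheme)

    raw_terms: dict[str, tuple[str, tuple[Span, ...], int]] = {}
    raw_events: dict[str, tuple[str, list[tuple[str, str]], int]] = {}
    raw_attrs: list[tuple[str, str, int]] = []

    for line_no, line in enumerate(ann.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        ann_id = fields[0]
        if ann_id.startswith("T"):
            if len(fields) < 2:
                raise StandoffParseError("term line needs a label field", line_no)
            head = fields[1]
            label, _, span_spec = head.partition(" ")
            if not span_spec:
                raise StandoffParseError(f"term line missing offsets: {head!r}", line_no)
            spans = _parse_spans(span_spec, line_no, len(text))
            surface = " ".join(text[s.start : s.end] for s in spans)
            if len(fields) >= 3 and fields[2] != surface:
                raise StandoffParseError(
                    f"mention text {fields[2]!r} does not match document "
                    f"substring {surface!r}",
                    line_no,
                )
            if ann_id in raw_terms:
                raise StandoffParseError(f"duplicate term id {ann_id!r}", line_no)
            raw_terms[ann_id] = (label, spans, line_no)
        elif ann_id.startswith("E"):
            if len(fields) < 2:
                raise StandoffParseError("event line needs an argument field", line_no)
            parts = fields[1].split()
            if not parts:
                raise StandoffParseError("empty event line", line_no)
            etype, _, trigger_ref = parts[0].partition(":")
            if not trigger_ref:
                raise StandoffParseError(f"event head {parts[0]!r} lacks trigger", line_no)
            args = []
            for p in parts[1:]:
                role, _, target = p.partition(":")
                if not target:
                    raise StandoffParseError(f"bad event argument {p!r}", line_no)
                args.append((_strip_role_index(role).upper(), target))
            if ann_id in raw_events:
                raise StandoffParseError(f"duplicate event id {ann_id!r}", line_no)
            raw_events[ann_id] = (trigger_ref, args, line_no)
        elif ann_id.startswith("A") or ann_id.startswith("M"):
            if len(fields) < 2:
                raise StandoffParseError("attribute line needs a value field", line_no)
            parts = fields[1].split()
            if len(parts) < 2:
                raise StandoffParseError(f"bad attribute {fields[1]!r}", line_no)
            raw_attrs.append((parts[0], parts[1], line_no))
        else:
            raise StandoffParseError(f"unsupported annotation id {ann_id!r}", line_no)

    categories = {c.upper(): c for c in scheme.entity_categories}
    qtypes = {q.upper(): q for q in scheme.question_types}

    entity_ids: set[str] = set()
    trigger_ids: set[str] = set()
    sentinel_ids: set[str] = set()
    entities: dict[str, EntityAnn] = {}
    triggers: dict[str, TriggerAnn] = {}
    for tid, (label, spans, line_no) in raw_terms.items():
        up = label.upper()
        mention = Mention(spans=spans, text=" ".join(text[s.start : s.end] for s in spans))
        if up in categories:
            entities[tid] = EntityAnn(id=tid, category=categories[up], mention=mention)
            entity_ids.add(tid)
        elif up in qtypes:
            triggers[tid] = TriggerAnn(id=tid, qtype=qtypes[up], mention=mention)
            trigger_ids.add(tid)
        elif up == SENTINEL_LABEL:
            sentinel_ids.add(tid)
        else:
            raise StandoffParseError(
                f"term label {label!r} is neither an entity category nor a "
                f"question type of scheme {scheme.name}",
                line_no,
            )

    frames: dict[str, FrameAnn] = {}
    for eid, (trigger_ref, args, line_no) in raw_events.items():
        if trigger_ref not in trigger_ids:
            raise StandoffParseError(
                f"event {eid} references {trigger_ref!r}, which is not a "
                "question-trigger term",
                line_no,
            )
        for role, target in args:
            if target not in entity_ids:
                raise StandoffParseError(
                    f"event {eid} argument {role}:{target} does not resolve "
                    "to an entity term",
                    line_no,
                )
        frames[eid] = FrameAnn(id=eid, trigger_ref=trigger_ref, args=tuple(args))

    labels: set[str] = set()
    topic_ids: set[str] = set()
    frame_attrs: dict[str, set[str]] = {}
    for name, target, line_no in raw_attrs:
        up = name.upper()
        if up in TOPIC_ALIASES:
            if target not in entity_ids:
                raise StandoffParseError(
                    f"topic attribute targets {target!r}, not an entity term", line_no
                )
            topic_ids.add(target)
        elif up in EXCLUSION_LABELS:
            if target not in sentinel_ids:
                raise StandoffParseError(
                    f"question label {name} must target the {SENTINEL_LABEL} "
                    f"sentinel term, got {target!r}",
                    line_no,
                )
            labels.add(up)
        elif target in frames:
            frame_attrs.setdefault(target, set()).add(up)
        else:
            raise StandoffParseError(
                f"attribute {name!r} on {target!r} is neither a topic flag, a "
                "question label, nor a frame attribute",
                line_no,
            )

    return QuestionDoc(
        doc_id=doc_id,
        text=text,
        entities=[
            EntityAnn(e.id, e.category, e.mention, is_topic=e.id in topic_ids)
            for e in entities.values()
        ],
        triggers=list(triggers.values()),
        frames=[
            FrameAnn(f.id, f.trigger_ref, f.args, frozenset(frame_attrs.get(f.id, ())))
            for f in frames.values()
        ],
        labels=frozenset(labels),
    )


def write_standoff(doc: QuestionDoc) -> str:
    """Serialize a document's annotations to a standoff string.

    Identifiers are renumbered; re-parsing the output yields a document
    semantically equal to the input (same annotations up to id renaming).
    """
    doc._check_refs()  # refuse structurally corrupt documents
    lines: list[str] = []
    t_counter = e_counter = a_counter = 0
    id_map: dict[str, str] = {}

    def term_line(label: str, mention: Mention) -> str:
        nonlocal t_counter
        t_counter += 1
        tid = f"T{t_counter}"
        span_spec = ";".join(f"{s.start} {s.end}" for s in mention.spans)
        return_id = tid
        lines.append(f"{tid}\t{label} {span_spec}\t{mention.text}")
        return return_id

    for ent in doc.entities:
        id_map[ent.id] = term_line(ent.category, ent.mention)
    for trg in doc.triggers:
        id_map[trg.id] = term_line(trg.qtype, trg.mention)

    for frame in doc.frames:
        e_counter += 1
        eid = f"E{e_counter}"
        id_map[frame.id] = eid
        qtype = doc.frame_qtype(frame)
        role_counts: dict[str, int] = {}
        parts = [f"{qtype}:{id_map[frame.trigger_ref]}"]
        for role, target in frame.args:
            n = role_counts.get(role, 0) + 1
            role_counts[role] = n
            suffix = "" if n == 1 else str(n)
            parts.append(f"{role}{suffix}:{id_map[target]}")
        lines.append(f"{eid}\t{' '.join(parts)}")

    for ent in doc.entities:
        if ent.is_topic:
            a_counter += 1
            lines.append(f"A{a_counter}\tTopic {id_map[ent.id]}")
    for frame in doc.frames:
        for attr in sorted(frame.attributes):
            a_counter += 1
            lines.append(f"A{a_counter}\t{attr} {id_map[frame.id]}")

    if doc.labels:
        end = max(len(doc.text), 1)
        sentinel = term_line(SENTINEL_LABEL, Mention.from_text(doc.text or " ", [(0, end)])) \
            if doc.text else None
        if sentinel is None:  # pragma: no cover - labelled doc with empty text
            raise ValueError("cannot anchor question labels on an empty document")
        for label in sorted(doc.labels):
            a_counter += 1
            lines.append(f"A{a_counter}\t{label} {sentinel}")

    return "\n".join(lines) + ("\n" if lines else "")


def load_corpus(
    root: str | Path,
    annotators: Sequence[str],
    scheme: SchemeDefinition | str,
) -> AnnotatedCorpus:
    """Load ``<root>/<annotator>/<doc_id>.{txt,ann}`` pairs into a corpus.

    Documents missing from any requested annotator are skipped with a
    warning; the same doc_id with diverging text across annotators is an
    error because its offsets would be incomparable.
    """
    root = Path(root)
    if isinstance(scheme, str):
        scheme = load_scheme(scheme)

    per_annotator: dict[str, dict[str, Path]] = {}
    for annotator in annotators:
        adir = root / annotator
        if not adir.is_dir():
            raise FileNotFoundError(f"annotator directory missing: {adir}")
        per_annotator[annotator] = {
            p.stem: p for p in sorted(adir.glob("*.txt"))
        }

    doc_sets = [set(files) for files in per_annotator.values()]
    shared = set.intersection(*doc_sets) if doc_sets else set()
    for annotator, files in per_annotator.items():
        for doc_id in sorted(set(files) - shared):
            logger.warning(
                "doc %s present for annotator %s only; skipping", doc_id, annotator
            )

    corpus = AnnotatedCorpus(scheme=scheme.name)
    texts: dict[str, str] = {}
    for doc_id in sorted(shared):
        for annotator in annotators:
            txt_path = per_annotator[annotator][doc_id]
            text = txt_path.read_text(encoding="utf-8")
            if doc_id in texts and texts[doc_id] != text:
                raise ValueError(
                    f"doc {doc_id!r}: text differs between annotators; "
                    "annotation offsets are incomparable"
                )
            texts[doc_id] = text
            ann_path = txt_path.with_suffix(".ann")
            ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
            doc = parse_standoff(text, ann, scheme, doc_id=doc_id)
            corpus.add(annotator, doc)
    return corpus


def save_corpus(corpus: AnnotatedCorpus, root: str | Path) -> None:
    """Write a corpus back out in the same directory layout load_corpus reads."""
    root = Path(root)
    for (doc_id, annotator), doc in corpus:
        adir = root / annotator
        adir.mkdir(parents=True, exist_ok=True)
        (adir / f"{doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (adir / f"{doc_id}.ann").write_text(write_standoff(doc), encoding="utf-8")
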