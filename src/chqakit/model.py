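"""Core data model for question-frame annotations.

A *question frame* is a structured representation of one sub-question in a
consumer health question: a typed trigger expression plus role-labelled
named-entity arguments, with THEME mandatory.  A document carries one
question's text together with its entity, trigger and frame layers from a
single annotator; a corpus maps ``(doc_id, annotator_id)`` pairs to
documents so that multiply-annotated questions can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "EXCLUSION_LABELS",
    "Span",
    "Mention",
    "EntityAnn",
    "TriggerAnn",
    "FrameAnn",
    "QuestionDoc",
    "AnnotatedCorpus",
]

#: Question-level labels marking items excluded from the final corpus.
EXCLUSION_LABELS = frozenset({"NOT_QUESTION", "NOT_ANSWERABLE", "DUPLICATE"})


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)`` in code points."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Mention:
    """A possibly discontinuous text anchor: one or more sorted spans."""

    spans: tuple[Span, ...]
    text: str

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("mention requires at least one span")
        for a, b in zip(self.spans, self.spans[1:]):
            if b.start < a.end:
                raise ValueError("mention spans must be sorted and non-overlapping")

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end

    def overlaps(self, other: "Mention") -> bool:
        """True when any fragment of one mention overlaps any of the other."""
        return any(a.overlaps(b) for a in self.spans for b in other.spans)

    @classmethod
    def from_text(cls, text: str, spans: Iterable[tuple[int, int]]) -> "Mention":
        sp = tuple(sorted(Span(s, e) for s, e in spans))
        return cls(spans=sp, text=" ".join(text[s.start : s.end] for s in sp))


@dataclass(frozen=True)
class EntityAnn:
    """A named-entity mention (category + anchor), optionally the topic."""

    id: str
    category: str
    mention: Mention
    is_topic: bool = False

    @property
    def key(self) -> tuple:
        """Content identity: category plus exact span list (topic flag aside)."""
        return (self.category, tuple((s.start, s.end) for s in self.mention.spans))


@dataclass(frozen=True)
class TriggerAnn:
    """The minimal text expression conveying a question type."""

    id: str
    qtype: str
    mention: Mention

    def __post_init__(self) -> None:
        if not self.qtype:
            raise ValueError("trigger requires a non-empty question type")

    @property
    def key(self) -> tuple:
        return (self.qtype, tuple((s.start, s.end) for s in self.mention.spans))


@dataclass(frozen=True)
class FrameAnn:
    """A question frame: trigger reference plus (role, entity-id) arguments.

    ``args`` is an ordered multiset; the same role may repeat (e.g. two
    THEME arguments in a COMPARISON frame).
    """

    id: str
    trigger_ref: str
    args: tuple[tuple[str, str], ...]
    attributes: frozenset[str] = frozenset()

    def role_args(self, role: str) -> tuple[str, ...]:
        return tuple(eid for r, eid in self.args if r == role)

    @property
    def theme_refs(self) -> tuple[str, ...]:
        return self.role_args("THEME")


@dataclass
class QuestionDoc:
    """One question's text and annotation layers from one annotator."""

    doc_id: str
    text: str
    entities: list[EntityAnn] = field(default_factory=list)
    triggers: list[TriggerAnn] = field(default_factory=list)
    frames: list[FrameAnn] = field(default_factory=list)
    labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.labels) - EXCLUSION_LABELS
        if bad:
            raise ValueError(f"unknown question-level labels: {sorted(bad)}")
        self._check_refs()

    def _check_refs(self) -> None:
        ids: set[str] = set()
        for ann in (*self.entities, *self.triggers, *self.frames):
            if ann.id in ids:
                raise ValueError(f"duplicate annotation id {ann.id!r}")
            ids.add(ann.id)
        entity_ids = {e.id for e in self.entities}
        trigger_ids = {t.id for t in self.triggers}
        for fr in self.frames:
            if fr.trigger_ref not in trigger_ids:
                raise ValueError(
                    f"frame {fr.id!r} references unknown trigger {fr.trigger_ref!r}"
                )
            for role, eid in fr.args:
                if eid not in entity_ids:
                    raise ValueError(
                        f"frame {fr.id!r} argument {role}:{eid} does not resolve"
                    )

    @property
    def is_excluded(self) -> bool:
        return bool(self.labels)

    def entity_by_id(self, eid: str) -> EntityAnn:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def trigger_by_id(self, tid: str) -> TriggerAnn:
        for t in self.triggers:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def frame_qtype(self, frame: FrameAnn) -> str:
        """A frame's question type is inherited from its trigger."""
        return self.trigger_by_id(frame.trigger_ref).qtype

    def topics(self) -> list[EntityAnn]:
        return [e for e in self.entities if e.is_topic]

    def with_annotations(
        self,
        entities: Iterable[EntityAnn] | None = None,
        triggers: Iterable[TriggerAnn] | None = None,
        frames: Iterable[FrameAnn] | None = None,
    ) -> "QuestionDoc":
        return QuestionDoc(
            doc_id=self.doc_id,
            text=self.text,
            entities=list(self.entities if entities is None else entities),
            triggers=list(self.triggers if triggers is None else triggers),
            frames=list(self.frames if frames is None else frames),
            labels=self.labels,
        )


@dataclass
class AnnotatedCorpus:
    """Documents from one or more annotators, keyed by (doc_id, annotator)."""

    scheme: str
    docs: dict[tuple[str, str], QuestionDoc] = field(default_factory=dict)

    def __post_init__(self) -> None:
        texts: dict[str, str] = {}
        for (doc_id, _), doc in self.docs.items():
            if doc_id in texts and texts[doc_id] != doc.text:
                raise ValueError(f"divergent text for doc_id {doc_id!r}")
            texts.setdefault(doc_id, doc.text)

    @property
    def doc_ids(self) -> list[str]:
        return sorted({d for d, _ in self.docs})

    @property
    def annotators(self) -> list[str]:
        return sorted({a for _, a in self.docs})

    def annotators_of(self, doc_id: str) -> list[str]:
        return sorted(a for d, a in self.docs if d == doc_id)

    def docs_of(self, annotator: str) -> dict[str, QuestionDoc]:
        return {d: doc for (d, a), doc in self.docs.items() if a == annotator}

    def shared_doc_ids(self, a: str, b: str) -> list[str]:
        return sorted(set(self.docs_of(a)) & set(self.docs_of(b)))

    def add(self, annotator: str, doc: QuestionDoc) -> None:
        key = (doc.doc_id, annotator)
        for (d, _), other in self.docs.items():
            if d == doc.doc_id and other.text != doc.text:
                raise ValueError(f"divergent text for doc_id {doc.doc_id!r}")
        self.docs[key] = doc

    def __iter__(self) -> Iterator[tuple[tuple[str, str], QuestionDoc]]:
        return iter(sorted(self.docs.items()))

    def __len__(self) -> int:
        return len(self.docs)
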