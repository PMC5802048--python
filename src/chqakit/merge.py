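"""Merging double annotations into a single set per question.

Three policies are provided.  AGREE keeps only annotations both annotators
produced — near-perfect precision, poor recall.  IAA_RANK takes, for each
question, the complete annotation set of whichever of its two annotators
has the higher average pairwise agreement with others.  The confidence
policy accepts every unanimous item and then admits disputed items whose
posterior confidence exceeds their semantic class's mean, visiting classes
in dependency order (entities, triggers, topics, frames) so that a topic
is only accepted once its entity is, and a frame only once its trigger and
all of its arguments are.

All policies yield a :class:`MergedQuestion` whose structural invariant —
no accepted frame or topic dangling over a rejected dependency — is
enforced on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .agreement import MatchSpec
from .confidence import SEMANTIC_CLASSES, CandidateItem, doc_item_keys
from .model import QuestionDoc

__all__ = [
    "MergePolicy",
    "MergedQuestion",
    "EvaluationReport",
    "merge_agree",
    "merge_rank",
    "merge_confidence",
    "class_mean_thresholds",
    "evaluate_against_gold",
    "merged_to_doc",
]


@dataclass(frozen=True)
class MergePolicy:
    """Which merging method to run, with its method-specific inputs."""

    method: str  # agree | iaa_rank | confidence
    rank_spec: MatchSpec | None = None
    class_thresholds: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("agree", "iaa_rank", "confidence"):
            raise ValueError(f"unknown merge method {self.method!r}")
        if self.method == "iaa_rank" and self.rank_spec is None:
            raise ValueError("iaa_rank requires rank_spec")
        if self.method != "iaa_rank" and self.rank_spec is not None:
            raise ValueError("rank_spec only applies to iaa_rank")


@dataclass
class MergedQuestion:
    """Accepted identity keys per semantic class, with provenance per item."""

    doc_id: str
    accepted: dict[str, set[tuple]] = field(default_factory=dict)
    provenance: dict[tuple, str] = field(default_factory=dict)
    dependencies: dict[tuple, tuple[tuple, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in SEMANTIC_CLASSES:
            self.accepted.setdefault(cls, set())
        self.check_consistency()

    def all_keys(self) -> set[tuple]:
        return set().union(*self.accepted.values())

    def is_consistent_with(self, deps: Iterable[tuple]) -> bool:
        keys = self.all_keys()
        return all(d in keys for d in deps)

    def check_consistency(self) -> None:
        keys = self.all_keys()
        for key, deps in self.dependencies.items():
            if key in keys:
                dangling = [d for d in deps if d not in keys]
                if dangling:
                    raise ValueError(
                        f"accepted item {key} dangles over rejected {dangling[0]}"
                    )

    def accept(self, item: CandidateItem, provenance: str) -> None:
        self.accepted[item.semantic_class].add(item.identity_key)
        self.provenance[item.identity_key] = provenance
        self.dependencies[item.identity_key] = tuple(item.depends_on)


def _consistency_filtered(
    doc_id: str, items: Sequence[CandidateItem], provenance: str
) -> MergedQuestion:
    """Accept items in dependency-class order, dropping dangling ones."""
    merged = MergedQuestion(doc_id=doc_id)
    by_class = {cls: [it for it in items if it.semantic_class == cls]
                for cls in SEMANTIC_CLASSES}
    for cls in SEMANTIC_CLASSES:
        for item in sorted(by_class[cls], key=lambda it: it.item_id):
            if merged.is_consistent_with(item.depends_on):
                merged.accept(item, provenance)
    merged.check_consistency()
    return merged


def merge_agree(items: Sequence[CandidateItem], doc_id: str | None = None) -> MergedQuestion:
    """Keep exactly the unanimous items, consistency-filtered.

    A unanimous frame whose trigger or argument was not itself unanimous is
    dropped rather than left dangling.
    """
    doc_id = doc_id if doc_id is not None else _single_doc_id(items)
    unanimous = [it for it in items if it.doc_id == doc_id and it.unanimous]
    return _consistency_filtered(doc_id, unanimous, provenance="agreed")


def _single_doc_id(items: Sequence[CandidateItem]) -> str:
    ids = {it.doc_id for it in items}
    if len(ids) != 1:
        raise ValueError(f"expected items from a single document, got {sorted(ids)}")
    return next(iter(ids))


def merge_rank(
    docs: Mapping[str, QuestionDoc], ranking: Sequence[str]
) -> MergedQuestion:
    """Take the complete annotation set of the higher-ranked annotator.

    ``docs`` maps the question's annotator ids to their documents;
    ``ranking`` is the global annotator ordering (best first), e.g. from
    :func:`chqakit.agreement.rank_annotators`.  The policy is wholesale:
    the preferred annotator's full set, nothing from the other.
    """
    missing = [a for a in docs if a not in ranking]
    if missing:
        raise ValueError(f"annotators missing from ranking: {missing}")
    preferred = min(docs, key=lambda a: ranking.index(a))
    doc = docs[preferred]
    merged = MergedQuestion(doc_id=doc.doc_id)
    for cls, keys in doc_item_keys(doc).items():
        for key, deps in keys.items():
            merged.accepted[cls].add(key)
            merged.provenance[key] = f"rank-preferred:{preferred}"
            merged.dependencies[key] = deps
    merged.check_consistency()
    return merged


def class_mean_thresholds(
    items: Sequence[CandidateItem],
    confidences: Mapping[str, float],
    population: str = "all",
) -> dict[str, float]:
    """Arithmetic mean confidence per semantic class.

    ``population`` selects the items averaged over: ``"all"`` (default) or
    ``"disagreed"`` only.  Classes with no items in the population are
    omitted.
    """
    if population not in ("all", "disagreed"):
        raise ValueError(f"unknown population {population!r}")
    sums: dict[str, list[float]] = {}
    for it in items:
        if population == "disagreed" and it.unanimous:
            continue
        if it.item_id not in confidences:
            raise KeyError(f"item {it.item_id!r} has no confidence score")
        sums.setdefault(it.semantic_class, []).append(confidences[it.item_id])
    return {cls: sum(v) / len(v) for cls, v in sums.items()}


def merge_confidence(
    items: Sequence[CandidateItem],
    confidences: Mapping[str, float],
    thresholds: Mapping[str, float],
    doc_id: str | None = None,
) -> MergedQuestion:
    """Unanimous items plus disputed items beating their class threshold.

    Agreement overrides the threshold: a unanimous item is accepted however
    low its confidence.  Disputed items are visited class-by-class in
    dependency order and, within a class, by descending confidence; each is
    accepted iff its confidence is strictly above its class threshold *and*
    it is consistent with what has been accepted so far (entities and
    triggers are atomic and always consistent; a topic needs its entity; a
    frame needs its trigger and all arguments).
    """
    doc_id = doc_id if doc_id is not None else _single_doc_id(items)
    doc_items = [it for it in items if it.doc_id == doc_id]
    unanimous = [it for it in doc_items if it.unanimous]
    disputed = [it for it in doc_items if not it.unanimous]
    for it in disputed:
        if it.item_id not in confidences:
            raise KeyError(f"disputed item {it.item_id!r} has no confidence score")

    merged = _consistency_filtered(doc_id, unanimous, provenance="agreed")
    for cls in SEMANTIC_CLASSES:
        pool = sorted(
            (it for it in disputed if it.semantic_class == cls),
            key=lambda it: (-confidences[it.item_id], it.item_id),
        )
        threshold = thresholds.get(cls)
        for item in pool:
            if threshold is None or confidences[item.item_id] <= threshold:
                continue
            if merged.is_consistent_with(item.depends_on):
                merged.accept(item, provenance="above-threshold")
    merged.check_consistency()
    return merged


# ---------------------------------------------------------------------------
# evaluation against adjudicated gold


@dataclass
class EvaluationReport:
    """Micro P/R/F1 of merged sets vs gold, pooled and per layer."""

    overall: tuple[int, int, int]  # tp, fp, fn
    per_layer: dict[str, tuple[int, int, int]]

    @staticmethod
    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    @property
    def precision(self) -> float:
        return self._prf(*self.overall)[0]

    @property
    def recall(self) -> float:
        return self._prf(*self.overall)[1]

    @property
    def f1(self) -> float:
        return self._prf(*self.overall)[2]

    def layer_scores(self, layer: str) -> tuple[float, float, float]:
        return self._prf(*self.per_layer[layer])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for layer, counts in [("all", self.overall), *sorted(self.per_layer.items())]:
            p, r, f = self._prf(*counts)
            rows.append(
                {"layer": layer, "tp": counts[0], "fp": counts[1], "fn": counts[2],
                 "precision": p, "recall": r, "f1": f}
            )
        return pd.DataFrame(rows)


def evaluate_against_gold(
    merged: Mapping[str, MergedQuestion] | Sequence[MergedQuestion],
    gold: Mapping[str, QuestionDoc],
    layers: Sequence[str] = SEMANTIC_CLASSES,
) -> EvaluationReport:
    """Compare merged identity-key sets with an adjudicated gold standard.

    Matching is by canonical content (exact identity keys); counts are
    pooled over all shared documents and over all requested layers for the
    overall triple, and reported per layer as well.
    """
    if not isinstance(merged, Mapping):
        merged = {mq.doc_id: mq for mq in merged}
    shared = sorted(set(merged) & set(gold))
    if not shared:
        raise ValueError("no overlapping doc_ids between merged sets and gold")
    per_layer = {cls: [0, 0, 0] for cls in layers}
    for doc_id in shared:
        gold_keys = doc_item_keys(gold[doc_id])
        for cls in layers:
            g = set(gold_keys[cls])
            m = merged[doc_id].accepted.get(cls, set())
            tp = len(g & m)
            per_layer[cls][0] += tp
            per_layer[cls][1] += len(m) - tp
            per_layer[cls][2] += len(g) - tp
    overall = tuple(sum(per_layer[cls][k] for cls in layers) for k in range(3))
    return EvaluationReport(
        overall=overall, per_layer={c: tuple(v) for c, v in per_layer.items()}
    )


def merged_to_doc(
    merged: MergedQuestion, sources: Sequence[QuestionDoc]
) -> QuestionDoc:
    """Materialize a merged key set back into annotations.

    Each accepted identity key is resolved against the source documents
    (either annotator's version supplies the concrete annotation; content
    is identical by construction of the keys).
    """
    for src in sources:
        if src.doc_id != merged.doc_id:
            raise ValueError("source document doc_id mismatch")
    text = sources[0].text
    from .model import EntityAnn, FrameAnn, Mention, Span, TriggerAnn

    def mention_from(spans: tuple) -> Mention:
        sp = tuple(Span(s, e) for s, e in spans)
        return Mention(spans=sp, text=" ".join(text[s.start : s.end] for s in sp))

    topic_keys = {key[1:] for key in merged.accepted["topic"]}
    entities: dict[tuple, EntityAnn] = {}
    for idx, key in enumerate(sorted(merged.accepted["entity"]), start=1):
        _, category, spans = key
        entities[(category, spans)] = EntityAnn(
            id=f"T{idx}", category=category, mention=mention_from(spans),
            is_topic=(category, spans) in topic_keys,
        )
    triggers: dict[tuple, TriggerAnn] = {}
    for idx, key in enumerate(sorted(merged.accepted["trigger"]), start=1):
        _, qtype, spans = key
        triggers[(qtype, spans)] = TriggerAnn(
            id=f"Q{idx}", qtype=qtype, mention=mention_from(spans)
        )
    frames = []
    for idx, key in enumerate(sorted(merged.accepted["frame"]), start=1):
        _, qtype, trig_spans, arg_keys = key
        frames.append(
            FrameAnn(
                id=f"E{idx}",
                trigger_ref=triggers[(qtype, trig_spans)].id,
                args=tuple((role, entities[ekey].id) for role, ekey in arg_keys),
            )
        )
    return QuestionDoc(
        doc_id=merged.doc_id,
        text=text,
        entities=list(entities.values()),
        triggers=list(triggers.values()),
        frames=frames,
        labels=sources[0].labels,
    )
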