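"""Pairwise inter-annotator agreement as micro-averaged F1.

Agreement between two annotators is measured by taking one side as the
gold standard and pooling true/false positive counts over all shared
documents (micro-averaging).  Mentions are compared under an exact
criterion (identical fragment lists) or an approximate one (any-fragment
overlap).  Frames are compared under four variants crossing {full, core}
× {trigger, type}: *core* requires the trigger criterion plus equal THEME
argument sets, *full* additionally equal non-THEME role arguments; the
``_trigger`` variants compare trigger mentions while ``_type`` variants
compare only the normalized question type.

Where overlap relaxation makes pairings ambiguous, candidates are resolved
by maximum-cardinality bipartite matching rather than greedily: this makes
the counts independent of annotation order and guarantees that relaxing
the criterion can never lower F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .model import AnnotatedCorpus, EntityAnn, FrameAnn, Mention, QuestionDoc, TriggerAnn

__all__ = [
    "LAYERS",
    "FRAME_VARIANTS",
    "MatchSpec",
    "PairScore",
    "AgreementReport",
    "match_mentions",
    "pairwise_f1",
    "agreement_matrix",
    "rank_annotators",
]

LAYERS = ("entity", "trigger", "qtype", "topic", "frame")
FRAME_VARIANTS = ("full_trigger", "full_type", "core_trigger", "core_type")
MODES = ("exact", "approximate")


@dataclass(frozen=True)
class MatchSpec:
    """What to compare and how strictly."""

    layer: str
    mode: str = "exact"
    frame_variant: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; valid: {LAYERS}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid: {MODES}")
        if (self.layer == "frame") != (self.frame_variant is not None):
            raise ValueError("frame_variant must be set exactly when layer='frame'")
        if self.frame_variant is not None and self.frame_variant not in FRAME_VARIANTS:
            raise ValueError(
                f"unknown frame variant {self.frame_variant!r}; valid: {FRAME_VARIANTS}"
            )

    def __str__(self) -> str:
        v = f":{self.frame_variant}" if self.frame_variant else ""
        return f"{self.layer}{v}/{self.mode}"


@dataclass(frozen=True)
class PairScore:
    """Pooled counts and derived scores for one annotator pair and spec."""

    annotator_a: str
    annotator_b: str
    spec: MatchSpec
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def swapped(self) -> "PairScore":
        """The same comparison with the other annotator taken as gold."""
        return PairScore(self.annotator_b, self.annotator_a, self.spec,
                         self.tp, self.fn, self.fp)


# ---------------------------------------------------------------------------
# mention and frame compatibility


def _mentions_compatible(a: Mention, b: Mention, mode: str) -> bool:
    if mode == "exact":
        return tuple(a.spans) == tuple(b.spans)
    return a.overlaps(b)


def _item_compatible(a, b, mode: str) -> bool:
    """Label + mention criterion for entity/trigger/topic items."""
    label_a = a.category if isinstance(a, EntityAnn) else a.qtype
    label_b = b.category if isinstance(b, EntityAnn) else b.qtype
    return label_a == label_b and _mentions_compatible(a.mention, b.mention, mode)


def _max_matching(
    n_a: int, n_b: int, compatible: Callable[[int, int], bool]
) -> list[tuple[int, int]]:
    """Maximum-cardinality one-to-one pairing between two indexed sides."""
    edges = [(i, j) for i in range(n_a) for j in range(n_b) if compatible(i, j)]
    if not edges:
        return []
    g = nx.Graph()
    left = [("a", i) for i in range(n_a)]
    g.add_nodes_from(left, bipartite=0)
    g.add_nodes_from([("b", j) for j in range(n_b)], bipartite=1)
    g.add_edges_from((("a", i), ("b", j)) for i, j in edges)
    matching = nx.bipartite.maximum_matching(g, top_nodes=left)
    return sorted(
        (u[1], v[1]) for u, v in matching.items() if u[0] == "a" and v[0] == "b"
    )


def match_mentions(
    a: Sequence[EntityAnn | TriggerAnn],
    b: Sequence[EntityAnn | TriggerAnn],
    mode: str = "exact",
) -> list[tuple[int, int]]:
    """One-to-one maximum pairing of mention-bearing annotations.

    Items pair only when their labels (entity category or question type)
    are equal and their mentions satisfy the span criterion.  Returns index
    pairs ``(i, j)`` into ``a`` and ``b``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    return _max_matching(len(a), len(b), lambda i, j: _item_compatible(a[i], b[j], mode))


@dataclass(frozen=True)
class _FrameView:
    """A frame resolved against its document for comparison."""

    qtype: str
    trigger_mention: Mention
    themes: tuple[EntityAnn, ...]
    others: tuple[tuple[str, EntityAnn], ...]

    @classmethod
    def of(cls, frame: FrameAnn, doc: QuestionDoc) -> "_FrameView":
        trigger = doc.trigger_by_id(frame.trigger_ref)
        themes = tuple(doc.entity_by_id(eid) for eid in frame.theme_refs)
        others = tuple(
            (role, doc.entity_by_id(eid)) for role, eid in frame.args if role != "THEME"
        )
        return cls(trigger.qtype, trigger.mention, themes, others)


def _arg_sets_match(
    a: Sequence[EntityAnn], b: Sequence[EntityAnn], mode: str
) -> bool:
    """True when the two argument lists admit a perfect one-to-one pairing."""
    if len(a) != len(b):
        return False
    pairs = _max_matching(len(a), len(b), lambda i, j: _item_compatible(a[i], b[j], mode))
    return len(pairs) == len(a)


def _frames_compatible(a: _FrameView, b: _FrameView, variant: str, mode: str) -> bool:
    if a.qtype != b.qtype:
        return False
    if variant.endswith("_trigger") and not _mentions_compatible(
        a.trigger_mention, b.trigger_mention, mode
    ):
        return False
    if not _arg_sets_match(a.themes, b.themes, mode):
        return False
    if variant.startswith("full"):
        roles_a = {r for r, _ in a.others}
        roles_b = {r for r, _ in b.others}
        if roles_a != roles_b:
            return False
        for role in roles_a:
            ents_a = [e for r, e in a.others if r == role]
            ents_b = [e for r, e in b.others if r == role]
            if not _arg_sets_match(ents_a, ents_b, mode):
                return False
    return True


# ---------------------------------------------------------------------------
# per-document true-positive counting


def _doc_counts(
    gold: QuestionDoc, pred: QuestionDoc, spec: MatchSpec,
    qtype_filter: str | None = None,
) -> tuple[int, int, int]:
    """(tp, n_gold, n_pred) for one shared document."""
    if spec.layer == "qtype":
        # normalized question types, aligned one-to-one per document by count
        from collections import Counter

        ca = Counter(t.qtype for t in gold.triggers)
        cb = Counter(t.qtype for t in pred.triggers)
        if qtype_filter is not None:
            ca = Counter({qtype_filter: ca[qtype_filter]})
            cb = Counter({qtype_filter: cb[qtype_filter]})
        tp = sum(min(ca[t], cb[t]) for t in ca.keys() & cb.keys())
        return tp, sum(ca.values()), sum(cb.values())

    if spec.layer in ("entity", "trigger", "topic"):
        if spec.layer == "entity":
            items_a, items_b = gold.entities, pred.entities
        elif spec.layer == "trigger":
            items_a, items_b = gold.triggers, pred.triggers
        else:
            items_a, items_b = gold.topics(), pred.topics()
        if qtype_filter is not None and spec.layer == "trigger":
            items_a = [t for t in items_a if t.qtype == qtype_filter]
            items_b = [t for t in items_b if t.qtype == qtype_filter]
        pairs = match_mentions(items_a, items_b, spec.mode)
        return len(pairs), len(items_a), len(items_b)

    # frames
    va = [_FrameView.of(f, gold) for f in gold.frames]
    vb = [_FrameView.of(f, pred) for f in pred.frames]
    if qtype_filter is not None:
        va = [v for v in va if v.qtype == qtype_filter]
        vb = [v for v in vb if v.qtype == qtype_filter]
    pairs = _max_matching(
        len(va), len(vb),
        lambda i, j: _frames_compatible(va[i], vb[j], spec.frame_variant, spec.mode),
    )
    return len(pairs), len(va), len(vb)


def pairwise_f1(
    gold: Mapping[str, QuestionDoc],
    pred: Mapping[str, QuestionDoc],
    spec: MatchSpec,
    annotator_a: str = "gold",
    annotator_b: str = "pred",
    qtype_filter: str | None = None,
) -> PairScore:
    """Micro-averaged F1 over all shared documents, one side taken as gold."""
    shared = sorted(set(gold) & set(pred))
    if not shared:
        raise ValueError("no shared documents between the two annotation sets")
    tp = n_gold = n_pred = 0
    for doc_id in shared:
        t, g, p = _doc_counts(gold[doc_id], pred[doc_id], spec, qtype_filter)
        tp += t
        n_gold += g
        n_pred += p
    return PairScore(annotator_a, annotator_b, spec, tp=tp, fp=n_pred - tp, fn=n_gold - tp)


# ---------------------------------------------------------------------------
# corpus-level report


@dataclass
class AgreementReport:
    """All pair scores plus per-spec summaries and per-type breakdown.

    The question-type layer aligns types one-to-one within each document
    (per-document count alignment), noted here because pooling counts
    corpus-wide would be a different statistic.
    """

    pair_scores: dict[tuple[str, str, MatchSpec], PairScore] = field(default_factory=dict)
    per_type: dict[tuple[str, str, MatchSpec, str], PairScore] = field(default_factory=dict)

    def scores_for(self, spec: MatchSpec) -> list[PairScore]:
        return [s for (a, b, sp), s in sorted(self.pair_scores.items()) if sp == spec]

    def summary(self, spec: MatchSpec) -> tuple[float, float, float]:
        """(average, min, max) of pair F1s for a spec."""
        scores = self.scores_for(spec)
        if not scores:
            raise KeyError(f"no scores for spec {spec}")
        f1s = [s.f1 for s in scores]
        return sum(f1s) / len(f1s), min(f1s), max(f1s)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "annotator_a": s.annotator_a,
                "annotator_b": s.annotator_b,
                "layer": s.spec.layer,
                "variant": s.spec.frame_variant or "",
                "mode": s.spec.mode,
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "precision": s.precision,
                "recall": s.recall,
                "f1": s.f1,
            }
            for _, s in sorted(self.pair_scores.items(), key=lambda kv: str(kv[0]))
        ]
        return pd.DataFrame(rows)

    def per_type_frame(self) -> pd.DataFrame:
        """Average trigger/type agreement per question type (Table-15 shape)."""
        acc: dict[tuple[str, str], list[float]] = {}
        for (a, b, spec, qt), score in self.per_type.items():
            col = "trigger" if spec.layer == "trigger" else "type"
            acc.setdefault((qt, col), []).append(score.f1)
        qtypes = sorted({qt for qt, _ in acc})
        rows = []
        for qt in qtypes:
            row = {"question_type": qt}
            for col in ("trigger", "type"):
                vals = acc.get((qt, col))
                row[col] = sum(vals) / len(vals) if vals else float("nan")
            rows.append(row)
        return pd.DataFrame(rows)


def agreement_matrix(
    corpus: AnnotatedCorpus,
    specs: Sequence[MatchSpec],
    per_type_breakdown: bool = False,
) -> AgreementReport:
    """One PairScore per unordered annotator pair (with shared docs) and spec."""
    annotators = corpus.annotators
    report = AgreementReport()
    any_pair = False
    for i, a in enumerate(annotators):
        for b in annotators[i + 1 :]:
            shared = corpus.shared_doc_ids(a, b)
            if not shared:
                continue
            any_pair = True
            docs_a = {d: corpus.docs[(d, a)] for d in shared}
            docs_b = {d: corpus.docs[(d, b)] for d in shared}
            for spec in specs:
                report.pair_scores[(a, b, spec)] = pairwise_f1(
                    docs_a, docs_b, spec, annotator_a=a, annotator_b=b
                )
            if per_type_breakdown:
                qtypes = sorted(
                    {t.qtype for d in (*docs_a.values(), *docs_b.values())
                     for t in d.triggers}
                )
                for qt in qtypes:
                    for spec in (MatchSpec("trigger"), MatchSpec("qtype")):
                        report.per_type[(a, b, spec, qt)] = pairwise_f1(
                            docs_a, docs_b, spec, annotator_a=a, annotator_b=b,
                            qtype_filter=qt,
                        )
    if not any_pair:
        raise ValueError("no annotator pair shares any document")
    return report


def rank_annotators(report: AgreementReport, spec: MatchSpec) -> list[str]:
    """Annotators by descending mean pair F1 for a spec; ties break by id."""
    sums: dict[str, list[float]] = {}
    for (a, b, sp), score in report.pair_scores.items():
        if sp != spec:
            continue
        sums.setdefault(a, []).append(score.f1)
        sums.setdefault(b, []).append(score.f1)
    if not sums:
        raise KeyError(f"report contains no scores for spec {spec}")
    means = {ann: sum(v) / len(v) for ann, v in sums.items()}
    return sorted(means, key=lambda ann: (-means[ann], ann))
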