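"""Adjudication-free annotation confidence estimation.

When a double-annotated corpus is too large to adjudicate, a posterior
confidence can be estimated for every produced annotation.  Each distinct
annotation proposition (an entity, trigger, topic or frame, identified by
its canonical content) becomes a *candidate item* with a present/absent
response from every annotator of its document.  An unsupervised
item-response model in the MACE family is then fitted by EM: each item has
a latent binary truth; each annotator either copies the truth (with
probability equal to their *competence*) or "spams" a label from their own
annotator-specific distribution.  The posterior probability that an item's
truth is *present* is its confidence.

The candidate space is the union of asserted annotations — the model
scores what annotators produced, it cannot hypothesize annotations nobody
asserted.  Frame items are scored independently of their argument items;
structural coupling is the merge step's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AnnotatedCorpus, QuestionDoc

__all__ = [
    "SEMANTIC_CLASSES",
    "CandidateItem",
    "ConfidenceModelConfig",
    "ConfidenceTable",
    "ItemResponseModel",
    "build_candidates",
    "doc_item_keys",
    "agree_subset",
    "fit_item_response",
    "score",
]

#: Dependency order: an item may only depend on items of earlier classes.
SEMANTIC_CLASSES = ("entity", "trigger", "topic", "frame")


@dataclass(frozen=True)
class CandidateItem:
    """One deduplicated annotation proposition with per-annotator responses.

    ``identity_key`` is the canonical content (category+spans for an
    entity, question type+spans for a trigger, the underlying entity key
    for a topic, and type+trigger spans+sorted role arguments for a frame)
    and is unique within ``(doc_id, semantic_class)``.  ``depends_on``
    lists the identity keys of items this one structurally requires.
    """

    item_id: str
    doc_id: str
    semantic_class: str
    identity_key: tuple
    responses: Mapping[str, bool]
    depends_on: tuple[tuple, ...] = ()

    def __post_init__(self) -> None:
        if self.semantic_class not in SEMANTIC_CLASSES:
            raise ValueError(f"unknown semantic class {self.semantic_class!r}")
        if not any(self.responses.values()):
            raise ValueError("candidate item must be asserted by at least one annotator")

    @property
    def unanimous(self) -> bool:
        return all(self.responses.values())


def doc_item_keys(doc: QuestionDoc) -> dict[str, dict[tuple, tuple[tuple, ...]]]:
    """Canonical identity keys of one document, per semantic class.

    Returns ``{class: {identity_key: depends_on}}``.
    """
    out: dict[str, dict[tuple, tuple[tuple, ...]]] = {
        c: {} for c in SEMANTIC_CLASSES
    }
    for ent in doc.entities:
        key = ("entity",) + ent.key
        out["entity"][key] = ()
        if ent.is_topic:
            out["topic"][("topic",) + ent.key] = (key,)
    for trg in doc.triggers:
        out["trigger"][("trigger",) + trg.key] = ()
    for frame in doc.frames:
        trigger = doc.trigger_by_id(frame.trigger_ref)
        arg_keys = tuple(
            sorted((role, doc.entity_by_id(eid).key) for role, eid in frame.args)
        )
        key = (
            "frame",
            trigger.qtype,
            tuple((s.start, s.end) for s in trigger.mention.spans),
            arg_keys,
        )
        deps = (("trigger",) + trigger.key,) + tuple(
            ("entity",) + doc.entity_by_id(eid).key for _, eid in frame.args
        )
        out["frame"][key] = tuple(dict.fromkeys(deps))  # dedupe, keep order
    return out


def build_candidates(corpus: AnnotatedCorpus) -> list[CandidateItem]:
    """Candidate items for every multiply-annotated document of a corpus.

    The union of all annotators' annotations per document is deduplicated
    by identity key; each annotator's response is *present* iff their own
    annotation set contains the key.  A document seen by fewer than two
    annotators cannot yield disagreement data and is an error.
    """
    items: list[CandidateItem] = []
    for doc_id in corpus.doc_ids:
        annotators = corpus.annotators_of(doc_id)
        if len(annotators) < 2:
            raise ValueError(
                f"doc {doc_id!r} has {len(annotators)} annotator(s); need >= 2"
            )
        per_ann = {
            a: doc_item_keys(corpus.docs[(doc_id, a)]) for a in annotators
        }
        for cls in SEMANTIC_CLASSES:
            union: dict[tuple, tuple[tuple, ...]] = {}
            for a in annotators:
                union.update(per_ann[a][cls])
            for idx, key in enumerate(sorted(union)):
                responses = {a: key in per_ann[a][cls] for a in annotators}
                items.append(
                    CandidateItem(
                        item_id=f"{doc_id}/{cls}/{idx}",
                        doc_id=doc_id,
                        semantic_class=cls,
                        identity_key=key,
                        responses=responses,
                        depends_on=union[key],
                    )
                )
    return items


def agree_subset(items: Sequence[CandidateItem]) -> list[CandidateItem]:
    """Items every annotator asserted (the AGREE baseline's raw material)."""
    return [it for it in items if it.unanimous]


@dataclass(frozen=True)
class ConfidenceModelConfig:
    """EM hyperparameters; two-annotator data is sparse, so smoothing matters."""

    em_iterations: int = 50
    restarts: int = 10
    smoothing: float = 0.5
    seed: int = 13

    def __post_init__(self) -> None:
        if self.em_iterations < 1 or self.restarts < 1 or self.smoothing <= 0:
            raise ValueError("em_iterations, restarts must be >= 1 and smoothing > 0")


@dataclass
class ConfidenceTable:
    """Fitted per-item confidences and per-annotator competences."""

    confidences: dict[str, float]
    competence: dict[str, float]
    log_likelihood: float
    item_index: dict[str, CandidateItem] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_likelihood):
            raise ValueError("non-finite log-likelihood")
        for v in self.confidences.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"confidence {v} outside [0, 1]")
        for v in self.competence.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"competence {v} outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Delimited-friendly table: one row per item with responses."""
        annotators = sorted(self.competence)
        rows = []
        for item_id, conf in self.confidences.items():
            item = self.item_index.get(item_id)
            row = {
                "item_id": item_id,
                "doc_id": item.doc_id if item else "",
                "class": item.semantic_class if item else "",
                "identity_key": repr(item.identity_key) if item else "",
                "confidence": conf,
            }
            for a in annotators:
                resp = item.responses.get(a) if item else None
                row[f"resp_{a}"] = (
                    "" if resp is None else ("present" if resp else "absent")
                )
            rows.append(row)
        return pd.DataFrame(rows)


class ItemResponseModel:
    """MACE-style binary item-response model fitted by EM.

    Estimator-style interface: construct with hyperparameters, ``fit`` on a
    sequence of :class:`CandidateItem`, read fitted state from
    trailing-underscore attributes (``competence_``, ``confidence_``,
    ``log_likelihood_``, ``objective_path_``).

    Parameters
    ----------
    em_iterations : int
        EM iterations per restart.
    restarts : int
        Random restarts; the best penalized objective wins.
    smoothing : float
        Symmetric Dirichlet/Beta pseudo-count applied to the truth prior,
        each competence, and each spamming distribution.  Unsmoothed EM on
        two-annotator data collapses to 0/1 competences.
    seed : int
        Seed for restart initialization; fitting is bit-deterministic.
    """

    def __init__(
        self,
        em_iterations: int = 50,
        restarts: int = 10,
        smoothing: float = 0.5,
        seed: int = 13,
    ):
        self.em_iterations = em_iterations
        self.restarts = restarts
        self.smoothing = smoothing
        self.seed = seed

    # -- minimal estimator plumbing -------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "em_iterations": self.em_iterations,
            "restarts": self.restarts,
            "smoothing": self.smoothing,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "ItemResponseModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- EM core ---------------------------------------------------------
    def fit(self, items: Sequence[CandidateItem]) -> "ItemResponseModel":
        ConfidenceModelConfig(self.em_iterations, self.restarts, self.smoothing,
                              self.seed)  # validate
        if not items:
            raise ValueError("no candidate items")
        annotators = sorted({a for it in items for a in it.responses})
        if len(annotators) < 2:
            raise ValueError("item-response estimation requires >= 2 annotators")
        a_index = {a: j for j, a in enumerate(annotators)}
        n, m = len(items), len(annotators)
        # Y: observed label (1 present / 0 absent); M: responded mask
        Y = np.zeros((n, m), dtype=np.int8)
        M = np.zeros((n, m), dtype=bool)
        for i, it in enumerate(items):
            for a, present in it.responses.items():
                j = a_index[a]
                M[i, j] = True
                Y[i, j] = 1 if present else 0
        unanimous_present = np.array(
            [bool(M[i].any()) and bool((Y[i][M[i]] == 1).all()) for i in range(n)]
        )

        rng = np.random.default_rng(self.seed)
        candidates = []
        for _ in range(self.restarts):
            state = self._run_em(Y, M, rng)
            candidates.append(state)

        # Label-switching guard: prefer restarts whose unanimous-present
        # items score > 0.5; otherwise flip the best solution.
        flipped = False
        def guard(st) -> bool:
            if not unanimous_present.any():
                return True
            return float(st["gamma1"][unanimous_present].mean()) > 0.5

        passing = [st for st in candidates if guard(st)]
        pool = passing if passing else candidates
        best = max(pool, key=lambda st: st["objective"])
        gamma1 = best["gamma1"]
        if not passing:
            gamma1 = 1.0 - gamma1
            flipped = True

        self.annotators_ = annotators
        self.items_ = list(items)
        self.competence_ = dict(zip(annotators, best["c"].tolist()))
        self.confidence_ = {
            it.item_id: float(gamma1[i]) for i, it in enumerate(items)
        }
        self.prior_present_ = float(best["pi"][1])
        self.spamming_ = {
            a: (float(best["s"][j, 0]), float(best["s"][j, 1]))
            for a, j in a_index.items()
        }
        self.log_likelihood_ = float(best["loglik"])
        self.objective_path_ = best["path"]
        self.label_flipped_ = flipped
        if not np.isfinite(self.log_likelihood_):
            raise ValueError("EM produced a non-finite log-likelihood")
        return self

    def _run_em(self, Y: np.ndarray, M: np.ndarray, rng: np.random.Generator) -> dict:
        n, m = Y.shape
        alpha = float(self.smoothing)
        pi = np.array([0.5, 0.5])
        c = rng.uniform(0.3, 0.9, size=m)  # competences
        s = np.full((m, 2), 0.5)  # spamming distribution per annotator
        n_j = M.sum(axis=0)

        path: list[float] = []
        prev_obj = -np.inf
        gamma1 = np.full(n, 0.5)
        loglik = np.nan
        for _ in range(self.em_iterations):
            # E-step -----------------------------------------------------
            # emission prob of observed label given truth t, per (i, j)
            s_y = np.where(Y == 1, s[:, 1][None, :], s[:, 0][None, :])
            spam = (1.0 - c)[None, :] * s_y
            p_t1 = np.where(Y == 1, c[None, :] + spam, spam)
            p_t0 = np.where(Y == 0, c[None, :] + spam, spam)
            log_w1 = np.log(pi[1]) + np.where(M, np.log(p_t1), 0.0).sum(axis=1)
            log_w0 = np.log(pi[0]) + np.where(M, np.log(p_t0), 0.0).sum(axis=1)
            hi = np.maximum(log_w0, log_w1)
            log_z = hi + np.log(np.exp(log_w0 - hi) + np.exp(log_w1 - hi))
            loglik = float(log_z.sum())
            gamma1 = np.exp(log_w1 - log_z)
            gamma0 = 1.0 - gamma1

            # posterior that the response was a copy of the truth
            rho1 = np.where(Y == 1, c[None, :] / p_t1, 0.0)
            rho0 = np.where(Y == 0, c[None, :] / p_t0, 0.0)

            # M-step -----------------------------------------------------
            copies = np.where(
                M, gamma1[:, None] * rho1 + gamma0[:, None] * rho0, 0.0
            ).sum(axis=0)
            spam1 = np.where(
                M & (Y == 1),
                gamma1[:, None] * (1.0 - rho1) + gamma0[:, None],
                0.0,
            ).sum(axis=0)
            spam0 = np.where(
                M & (Y == 0),
                gamma0[:, None] * (1.0 - rho0) + gamma1[:, None],
                0.0,
            ).sum(axis=0)
            c = (copies + alpha) / (n_j + 2 * alpha)
            tot = spam0 + spam1 + 2 * alpha
            s = np.stack([(spam0 + alpha) / tot, (spam1 + alpha) / tot], axis=1)
            g1 = gamma1.sum()
            pi = np.array([(n - g1 + alpha), (g1 + alpha)]) / (n + 2 * alpha)

            # penalized objective (log-likelihood + conjugate log-priors);
            # MAP-EM guarantees this is non-decreasing
            obj = (
                loglik
                + alpha * np.log(pi).sum()
                + alpha * (np.log(c) + np.log1p(-c)).sum()
                + alpha * np.log(s).sum()
            )
            if obj < prev_obj - 1e-8 * max(1.0, abs(prev_obj)):
                raise AssertionError(
                    f"EM objective decreased: {prev_obj} -> {obj}"
                )
            prev_obj = obj
            path.append(float(obj))

        return {
            "pi": pi, "c": c, "s": s, "gamma1": gamma1,
            "loglik": loglik, "objective": prev_obj, "path": path,
        }

    def table(self) -> ConfidenceTable:
        """Fitted state packaged for serialization and merging."""
        return ConfidenceTable(
            confidences=dict(self.confidence_),
            competence=dict(self.competence_),
            log_likelihood=self.log_likelihood_,
            item_index={it.item_id: it for it in self.items_},
        )


def fit_item_response(
    items: Sequence[CandidateItem],
    config: ConfidenceModelConfig | None = None,
) -> ConfidenceTable:
    """Fit the item-response model and return its confidence table."""
    config = config or ConfidenceModelConfig()
    model = ItemResponseModel(
        em_iterations=config.em_iterations,
        restarts=config.restarts,
        smoothing=config.smoothing,
        seed=config.seed,
    )
    return model.fit(items).table()


def score(
    items: Sequence[CandidateItem], table: ConfidenceTable
) -> dict[str, float]:
    """Item-id → confidence, ordered by (doc_id, class, descending confidence)."""
    missing = [it.item_id for it in items if it.item_id not in table.confidences]
    if missing:
        raise KeyError(f"items not present in confidence table: {missing[:5]}")
    ordered = sorted(
        items,
        key=lambda it: (
            it.doc_id,
            SEMANTIC_CLASSES.index(it.semantic_class),
            -table.confidences[it.item_id],
            it.item_id,
        ),
    )
    return {it.item_id: table.confidences[it.item_id] for it in ordered}
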