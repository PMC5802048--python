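"""Synthetic corpora, query-log filtering, and corpus statistics.

The generator emulates the *structure* of a double-annotated consumer
health question corpus — template-built question texts with entity
mentions, typed triggers, frames with THEME plus optional roles, topic
attributes in the email scheme — not natural language.  Downstream
agreement, confidence and merge computations only consume offsets and
labels, so template text is sufficient to exercise them end to end.

Annotator noise is simulated per profile: each gold annotation is
reproduced with probability ``competence``, reproduced annotations may get
boundary jitter and label confusion, spurious annotations are added at a
Poisson rate, and frames whose trigger or arguments were dropped are
dropped too (structural closure).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
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
    "AnnotatorProfile",
    "GenConfig",
    "QueryRecord",
    "generate_gold",
    "corrupt_annotations",
    "build_noisy_corpus",
    "detect_question",
    "filter_records",
    "make_query_records",
    "simulate_item_responses",
    "corpus_stats",
    "tokenize",
]

GOLD_ANNOTATOR = "gold"

# Small category-tagged lexicons; single-token surface forms keep offset
# bookkeeping trivial and guarantee distinct spans for distinct slots.
_ENTITY_LEXICON: dict[str, list[str]] = {
    "PROBLEM": ["diabetes", "shingles", "anemia", "migraine", "eczema", "asthma"],
    "DRUG_SUPPLEMENT": ["atenolol", "metformin", "ibuprofen", "zinc", "insulin"],
    "PROCEDURE_DEVICE": ["biopsy", "stent", "dialysis", "implant"],
    "ANATOMY": ["liver", "knee", "gum", "spine"],
    "PERSON_POPULATION": ["daughter", "veteran", "infant", "mother"],
    "DIAGNOSTIC_PROCEDURE": ["mri", "colonoscopy", "xray"],
    "SUBSTANCE": ["iron", "alcohol", "caffeine", "mercury"],
    "FOOD": ["eggs", "meat", "bread"],
    "LIFESTYLE": ["smoking", "yoga", "running"],
    "MEASUREMENT": ["10mg", "2%"],
    "ORGANIZATION": ["navy", "hospital"],
    "PROFESSION": ["dermatologist", "surgeon"],
    "GENE_PROTEIN": ["brca1", "glut4"],
    "CELLULAR_ENTITY": ["hemoglobin", "platelets"],
    "GEOGRAPHIC_LOCATION": ["india", "texas"],
    "ORGANISM_FUNCTION": ["pregnancy", "digestion"],
    "OTHER": ["relapse"],
    "RESEARCH_CUE": ["latest", "new"],
}

# Commonly used trigger expressions per question type.
_TRIGGER_LEXICON: dict[str, list[str]] = {
    "COMPARISON": ["differences", "compare"],
    "INFORMATION": ["information", "types"],
    "OTHER_QUESTION": ["prepare", "cover"],
    "CAUSE": ["cause", "trigger"],
    "COMPLICATION": ["risk", "damage"],
    "DIAGNOSIS": ["diagnose", "detection"],
    "EFFECT": ["affect", "related"],
    "ASSOCIATION": ["affect", "related"],
    "FREQUENCY": ["statistics", "prevalence"],
    "INHERITANCE": ["genetic", "passed"],
    "LIFESTYLE_DIET": ["precautions", "okay"],
    "LOCATION": ["areas", "occur"],
    "PERSON_ORGANIZATION": ["find", "consult"],
    "PREVENTION": ["prevent", "avoid"],
    "PROGNOSIS": ["recovery", "outlook"],
    "SUPPORT_GROUP": ["support", "recommend"],
    "SUSCEPTIBILITY": ["transmitted", "spread"],
    "SYMPTOM": ["symptom", "normal"],
    "TREATMENT": ["cure", "help", "improve"],
    "ACTION": ["working", "acts"],
    "ALTERNATIVE": ["alternative", "replacement"],
    "CONTRAINDICATION": ["hurt", "avoid"],
    "COST": ["cost", "rate"],
    "DOSAGE": ["dosage", "administration"],
    "INDICATION": ["given", "for"],
    "INGREDIENT": ["made", "in"],
    "INTERACTION": ["reaction", "safe"],
    "LONG_TERM_EFFECT": ["longterm", "cause"],
    "OVERDOSE": ["overdose", "hurt"],
    "SIDE_EFFECT": ["sideeffect", "poisonous"],
    "STORAGE_DISPOSAL": ["expire", "stability"],
    "TAPERING": ["weaning", "withdrawal"],
    "USAGE": ["take", "applying"],
    "DIAGNOSE_ME": ["what", "is"],
    "TIME": ["when"],
    "DRUG_QUESTION": ["potent", "come"],
}

_FILLER = ["please", "tell", "me", "about", "my", "the", "and", "also", "i",
           "wonder", "if", "this", "really", "matters", "for", "us"]

# Default sampling weights mirror the corpus's printed frequency rank order:
# PROBLEM dominates entities; TREATMENT and INFORMATION dominate types.
_DEFAULT_ENTITY_WEIGHTS = {
    "PROBLEM": 35, "DRUG_SUPPLEMENT": 14, "PROCEDURE_DEVICE": 9, "ANATOMY": 8,
    "PERSON_POPULATION": 7, "DIAGNOSTIC_PROCEDURE": 6, "SUBSTANCE": 5,
    "FOOD": 3, "LIFESTYLE": 3, "MEASUREMENT": 2, "ORGANIZATION": 2,
    "PROFESSION": 2, "GENE_PROTEIN": 1, "CELLULAR_ENTITY": 1,
    "GEOGRAPHIC_LOCATION": 1, "ORGANISM_FUNCTION": 1, "OTHER": 1,
}
_DEFAULT_TYPE_WEIGHTS = {
    "TREATMENT": 20, "INFORMATION": 14, "CAUSE": 8, "DIAGNOSIS": 6,
    "SYMPTOM": 5, "SUSCEPTIBILITY": 4, "PREVENTION": 4, "USAGE": 4,
    "INDICATION": 3, "PROGNOSIS": 3, "COMPARISON": 2, "INTERACTION": 2,
    "COMPLICATION": 2, "PERSON_ORGANIZATION": 2, "COST": 1, "INGREDIENT": 1,
}


@dataclass(frozen=True)
class AnnotatorProfile:
    """Noise model for one simulated annotator.

    ``competence`` is the probability of reproducing a gold annotation;
    ``spurious_rate`` the expected number of invented annotations per
    document; ``span_jitter`` the maximum boundary perturbation in
    characters, applied to a kept mention with probability
    ``boundary_noise`` (annotators agree on most boundaries and disagree
    on some, rather than re-drawing every boundary); ``type_confusion``
    the probability of swapping a kept annotation's category or question
    type with a scheme sibling.
    """

    annotator_id: str
    competence: float = 0.9
    spurious_rate: float = 0.3
    span_jitter: int = 0
    type_confusion: float = 0.0
    boundary_noise: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.competence, self.type_confusion, self.boundary_noise):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.spurious_rate < 0 or self.span_jitter < 0:
            raise ValueError("spurious_rate and span_jitter must be >= 0")


@dataclass(frozen=True)
class GenConfig:
    """Shape of the generated gold corpus."""

    scheme: str = "chqa-email"
    n_questions: int = 20
    length: str = "mixed"  # short | long | mixed
    entity_weights: Mapping[str, float] | None = None
    type_weights: Mapping[str, float] | None = None
    frames_per_question: Sequence[float] = (0.55, 0.3, 0.15)  # P(1), P(2), P(3)
    keyword_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length not in ("short", "long", "mixed"):
            raise ValueError(f"unknown length regime {self.length!r}")
        if any(w < 0 for w in self.frames_per_question) or not sum(self.frames_per_question):
            raise ValueError("frames_per_question weights must be non-negative, not all zero")
        for weights in (self.entity_weights, self.type_weights):
            if weights is not None:
                if any(w < 0 for w in weights.values()):
                    raise ValueError("weights must be non-negative")
                if not any(w > 0 for w in weights.values()):
                    raise ValueError("at least one positive weight required")


@dataclass(frozen=True)
class QueryRecord:
    """One raw query with its optional exclusion label."""

    text: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (None, "NOT_QUESTION", "NOT_ANSWERABLE", "DUPLICATE"):
            raise ValueError(f"unknown label {self.label!r}")


def _pick(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    names = sorted(k for k, w in weights.items() if w > 0)
    w = np.array([weights[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=w / w.sum())]


class _TextBuilder:
    """Accumulates whitespace-joined tokens, tracking annotated spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add(self, token: str) -> tuple[int, int]:
        if self.parts:
            self.pos += 1  # separating space
        start = self.pos
        self.parts.append(token)
        self.pos += len(token)
        return start, self.pos

    @property
    def text(self) -> str:
        return " ".join(self.parts)


def generate_gold(config: GenConfig) -> AnnotatedCorpus:
    """Generate a schema-valid single-annotator ("gold") corpus.

    Every question has at least one valid frame; THEME categories respect
    the scheme's restrictions and cardinalities; the email scheme marks a
    topic entity per question.  Deterministic given ``config.seed``.
    """
    scheme = load_scheme(config.scheme)
    rng = np.random.default_rng(config.seed)
    e_weights = dict(config.entity_weights or _DEFAULT_ENTITY_WEIGHTS)
    t_weights = dict(config.type_weights or _DEFAULT_TYPE_WEIGHTS)
    e_weights = {k: v for k, v in e_weights.items() if k in scheme.entity_categories}
    t_weights = {k: v for k, v in t_weights.items() if k in scheme.question_types}
    if not t_weights or not any(v > 0 for v in t_weights.values()):
        raise ValueError("no positive question-type weight applies to this scheme")

    fpq = np.array(config.frames_per_question, dtype=float)
    fpq = fpq / fpq.sum()

    corpus = AnnotatedCorpus(scheme=scheme.name)
    for q in range(config.n_questions):
        doc = _generate_question(f"q{q:04d}", scheme, rng, e_weights, t_weights,
                                 fpq, config)
        corpus.add(GOLD_ANNOTATOR, doc)
    return corpus


def _theme_category(
    scheme: SchemeDefinition, qtype: str, rng: np.random.Generator,
    e_weights: Mapping[str, float],
) -> str:
    allowed = scheme.allowed_theme_categories(qtype)
    if not allowed:
        pool = {k: v for k, v in e_weights.items() if v > 0}
        return _pick(rng, pool)
    restricted = {k: e_weights.get(k, 1.0) or 1.0 for k in allowed}
    return _pick(rng, restricted)


def _surface(category: str, rng: np.random.Generator) -> str:
    words = _ENTITY_LEXICON.get(category, ["thing"])
    return words[rng.integers(len(words))]


def _generate_question(
    doc_id: str,
    scheme: SchemeDefinition,
    rng: np.random.Generator,
    e_weights: Mapping[str, float],
    t_weights: Mapping[str, float],
    fpq: np.ndarray,
    config: GenConfig,
) -> QuestionDoc:
    builder = _TextBuilder()
    entities: list[EntityAnn] = []
    triggers: list[TriggerAnn] = []
    frames: list[FrameAnn] = []
    counter = {"T": 0}

    def next_id(prefix: str) -> str:
        counter["T"] += 1
        return f"{prefix}{counter['T']}"

    long_doc = config.length == "long" or (
        config.length == "mixed" and rng.random() < 0.5
    )
    n_frames = 1 + int(rng.choice(len(fpq), p=fpq))
    keyword_role = "KEYWORD" if "KEYWORD" in scheme.roles else "RESTRICTOR"

    for f in range(n_frames):
        if long_doc:
            for _ in range(int(rng.integers(2, 6))):
                builder.add(_FILLER[rng.integers(len(_FILLER))])
        qtype = _pick(rng, t_weights)
        lo, _hi = scheme.theme_bounds(qtype)
        n_themes = max(lo, 1)

        builder.add("what")
        trig_word = _TRIGGER_LEXICON.get(qtype, ["about"])[0]
        t_start, t_end = builder.add(trig_word)
        trig = TriggerAnn(
            id=next_id("X"), qtype=qtype,
            mention=Mention((Span(t_start, t_end),), trig_word),
        )
        triggers.append(trig)

        args: list[tuple[str, str]] = []
        topic_candidate: EntityAnn | None = None
        for k in range(n_themes):
            if k:
                builder.add("and")
            category = _theme_category(scheme, qtype, rng, e_weights)
            word = _surface(category, rng)
            s, e = builder.add(word)
            ent = EntityAnn(
                id=next_id("X"), category=category,
                mention=Mention((Span(s, e),), word),
            )
            entities.append(ent)
            args.append(("THEME", ent.id))
            topic_candidate = topic_candidate or ent
        if rng.random() < config.keyword_prob:
            builder.add("with")
            category = _pick(rng, e_weights)
            word = _surface(category, rng)
            s, e = builder.add(word)
            ent = EntityAnn(
                id=next_id("X"), category=category,
                mention=Mention((Span(s, e),), word),
            )
            entities.append(ent)
            args.append((keyword_role, ent.id))
        frames.append(
            FrameAnn(id=next_id("F"), trigger_ref=trig.id, args=tuple(args))
        )
        if f == 0 and scheme.topic_required and topic_candidate is not None:
            idx = entities.index(topic_candidate)
            entities[idx] = replace(topic_candidate, is_topic=True)
    builder.add("?")

    return QuestionDoc(
        doc_id=doc_id, text=builder.text,
        entities=entities, triggers=triggers, frames=frames,
    )


# ---------------------------------------------------------------------------
# annotator noise


def _jitter_mention(
    mention: Mention, jitter: int, text_len: int, rng: np.random.Generator, text: str
) -> Mention:
    spans = []
    for sp in mention.spans:
        ds = int(rng.integers(-jitter, jitter + 1))
        de = int(rng.integers(-jitter, jitter + 1))
        if ds == 0 and de == 0:
            de = int(rng.choice([-1, 1])) * min(1, jitter)
        start = min(max(0, sp.start + ds), text_len - 1)
        end = max(start + 1, min(text_len, sp.end + de))
        spans.append(Span(start, end))
    spans = _deoverlap(sorted(spans))
    return Mention(tuple(spans), " ".join(text[s.start : s.end] for s in spans))


def _deoverlap(spans: list[Span]) -> list[Span]:
    out: list[Span] = []
    for sp in spans:
        if out and sp.start < out[-1].end:
            if sp.end <= out[-1].end:
                continue
            sp = Span(out[-1].end, sp.end)
        out.append(sp)
    return out


def corrupt_annotations(
    gold: AnnotatedCorpus, profile: AnnotatorProfile
) -> dict[str, QuestionDoc]:
    """Simulate one noisy annotator over a gold corpus.

    Returns that annotator's document set, keyed by doc_id.  Deterministic
    given ``profile.seed``.
    """
    scheme = load_scheme(gold.scheme)
    rng = np.random.default_rng(profile.seed)
    out: dict[str, QuestionDoc] = {}
    for doc_id in gold.doc_ids:
        annotators = gold.annotators_of(doc_id)
        src = gold.docs[(doc_id, annotators[0])]
        out[doc_id] = _corrupt_doc(src, profile, scheme, rng)
    return out


def _corrupt_doc(
    src: QuestionDoc,
    profile: AnnotatorProfile,
    scheme: SchemeDefinition,
    rng: np.random.Generator,
) -> QuestionDoc:
    text = src.text
    categories = sorted(scheme.entity_categories)
    qtypes = sorted(scheme.question_types)

    entities: list[EntityAnn] = []
    kept_entities: set[str] = set()
    for ent in src.entities:
        if rng.random() >= profile.competence:
            continue
        category = ent.category
        if profile.type_confusion and rng.random() < profile.type_confusion:
            siblings = [c for c in categories if c != category]
            category = siblings[rng.integers(len(siblings))]
        mention = ent.mention
        if profile.span_jitter and rng.random() < profile.boundary_noise:
            mention = _jitter_mention(mention, profile.span_jitter, len(text), rng, text)
        entities.append(EntityAnn(ent.id, category, mention, ent.is_topic))
        kept_entities.add(ent.id)

    triggers: list[TriggerAnn] = []
    kept_triggers: set[str] = set()
    for trg in src.triggers:
        if rng.random() >= profile.competence:
            continue
        qtype = trg.qtype
        if profile.type_confusion and rng.random() < profile.type_confusion:
            siblings = [t for t in qtypes if t != qtype]
            qtype = siblings[rng.integers(len(siblings))]
        mention = trg.mention
        if profile.span_jitter and rng.random() < profile.boundary_noise:
            mention = _jitter_mention(mention, profile.span_jitter, len(text), rng, text)
        triggers.append(TriggerAnn(trg.id, qtype, mention))
        kept_triggers.add(trg.id)

    frames: list[FrameAnn] = []
    for frame in src.frames:
        if rng.random() >= profile.competence:
            continue
        # structural closure: drop frames whose trigger or arguments vanished
        if frame.trigger_ref not in kept_triggers:
            continue
        if any(eid not in kept_entities for _, eid in frame.args):
            continue
        frames.append(frame)

    n_spurious = int(rng.poisson(profile.spurious_rate))
    for k in range(n_spurious):
        if len(text) < 2:
            break
        length = int(rng.integers(3, 9))
        start = int(rng.integers(0, max(1, len(text) - length)))
        end = min(len(text), start + length)
        mention = Mention((Span(start, end),), text[start:end])
        if rng.random() < 0.7:
            category = categories[rng.integers(len(categories))]
            entities.append(EntityAnn(f"S{k}", category, mention))
        else:
            qtype = qtypes[rng.integers(len(qtypes))]
            triggers.append(TriggerAnn(f"S{k}", qtype, mention))

    return QuestionDoc(
        doc_id=src.doc_id, text=text,
        entities=entities, triggers=triggers, frames=frames, labels=src.labels,
    )


def simulate_item_responses(
    n_items: int,
    competences: Mapping[str, float],
    prior_present: float = 0.7,
    spam_present: float = 0.5,
    seed: int = 0,
) -> "list":
    """Draw candidate items directly from the item-response model.

    Each item gets a latent binary truth (present with probability
    ``prior_present``); each annotator copies the truth with probability
    equal to their competence, otherwise emits *present* with probability
    ``spam_present``.  Items nobody asserted cannot exist in a union of
    annotations and are dropped, as in real candidate construction.  Used
    for parameter-recovery checks of the confidence model.

    The default truth prior reflects double-annotation regimes where about
    seven in ten pooled candidate propositions are correct, as implied by
    typical unanimous-subset precision/recall arithmetic; the default spam
    distribution is neutral between junk assertions and omissions.
    """
    from .confidence import CandidateItem

    rng = np.random.default_rng(seed)
    annotators = sorted(competences)
    items = []
    i = 0
    while len(items) < n_items:
        truth = rng.random() < prior_present
        responses = {}
        for a in annotators:
            if rng.random() < competences[a]:
                responses[a] = truth
            else:
                responses[a] = rng.random() < spam_present
        i += 1
        if not any(responses.values()):
            continue
        items.append(
            CandidateItem(
                item_id=f"sim{i:05d}/entity/0",
                doc_id=f"sim{i:05d}",
                semantic_class="entity",
                identity_key=("entity", "SIM", ((i, i + 1),)),
                responses=responses,
            )
        )
    return items


def build_noisy_corpus(
    gold: AnnotatedCorpus, profiles: Sequence[AnnotatorProfile]
) -> AnnotatedCorpus:
    """Corrupt a gold corpus with several annotator profiles at once."""
    corpus = AnnotatedCorpus(scheme=gold.scheme)
    for profile in profiles:
        for doc_id, doc in corrupt_annotations(gold, profile).items():
            corpus.add(profile.annotator_id, doc)
    return corpus


# ---------------------------------------------------------------------------
# query-log harvesting filters

_WH_WORDS = frozenset({"how", "what", "when", "where", "which", "who", "why"})
_AUXILIARIES = ("is it", "can", "could", "do", "does")


def detect_question(query: str, wh_anywhere: bool = True) -> bool:
    """True when a query looks like a natural-language question.

    Cues: a wh-word token (anywhere by default, start-anchored when
    ``wh_anywhere`` is False), a trailing question mark, or a leading
    auxiliary from (*is it, can, could, do, does*).  Case-insensitive and
    token-boundary aware.
    """
    q = query.strip().lower()
    if not q:
        return False
    if q.endswith("?"):
        return True
    tokens = re.findall(r"[a-z']+", q)
    if not tokens:
        return False
    wh_pool = tokens if wh_anywhere else tokens[:1]
    if any(t in _WH_WORDS for t in wh_pool):
        return True
    for aux in _AUXILIARIES:
        aux_tokens = aux.split()
        if tokens[: len(aux_tokens)] == aux_tokens:
            return True
    return False


def filter_records(
    records: Sequence[QueryRecord],
) -> tuple[list[QueryRecord], Counter]:
    """Drop labelled records; report removal counts per exclusion label."""
    removed: Counter = Counter()
    survivors: list[QueryRecord] = []
    for rec in records:
        if rec.label is None:
            survivors.append(rec)
        else:
            removed[rec.label] += 1
    return survivors, removed


def make_query_records(
    n_unlabelled: int,
    labelled: Mapping[str, int] | None = None,
    seed: int = 0,
) -> list[QueryRecord]:
    """Placeholder query records for exercising the exclusion filters."""
    rng = np.random.default_rng(seed)
    topics = _ENTITY_LEXICON["PROBLEM"] + _ENTITY_LEXICON["DRUG_SUPPLEMENT"]
    records = [
        QueryRecord(f"what causes {topics[rng.integers(len(topics))]}")
        for _ in range(n_unlabelled)
    ]
    for label, count in (labelled or {}).items():
        records.extend(
            QueryRecord(f"query {i} flagged", label=label) for i in range(count)
        )
    return records


# ---------------------------------------------------------------------------
# corpus statistics

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with punctuation split off."""
    return _TOKEN_RE.findall(text)


def corpus_stats(corpus: AnnotatedCorpus) -> dict[str, pd.DataFrame]:
    """Token, entity, trigger and frame distribution tables.

    Token statistics are over unique questions; annotation counts include
    every annotator's copy, so double-annotated questions count twice —
    the convention used when no adjudicated set exists.
    """
    if not len(corpus):
        raise ValueError("empty corpus")

    token_counts = {}
    for doc_id in corpus.doc_ids:
        annotator = corpus.annotators_of(doc_id)[0]
        token_counts[doc_id] = len(tokenize(corpus.docs[(doc_id, annotator)].text))
    counts = np.array(sorted(token_counts.values()))
    questions = pd.DataFrame(
        [{
            "n_questions": len(counts),
            "n_tokens": int(counts.sum()),
            "avg_tokens": float(counts.mean()),
            "min_tokens": int(counts.min()),
            "max_tokens": int(counts.max()),
            "std_tokens": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        }]
    )

    ent_counter: Counter = Counter()
    trig_counter: Counter = Counter()
    frame_counter: Counter = Counter()
    for _, doc in corpus:
        ent_counter.update(e.category for e in doc.entities)
        trig_counter.update(t.qtype for t in doc.triggers)
        frame_counter.update(doc.frame_qtype(f) for f in doc.frames)

    def table(counter: Counter, label: str) -> pd.DataFrame:
        total = sum(counter.values())
        rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            [
                {label: name, "count": cnt,
                 "percent": 100.0 * cnt / total if total else 0.0,
                 "rank": rank}
                for rank, (name, cnt) in enumerate(rows, start=1)
            ]
        )

    return {
        "questions": questions,
        "entities": table(ent_counter, "category"),
        "triggers": table(trig_counter, "question_type"),
        "frames": table(frame_counter, "question_type"),
    }
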