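"""Annotation schemes and semantic validation.

Two schemes are shipped as YAML data files: ``chqa-email`` (17 entity
categories, 33 question types, topic required, nested entities allowed)
and ``chqa-web`` (18 categories, 26 consolidated types, THEME type
restrictions lifted, no topic layer, no nesting).  Validation returns
:class:`Violation` records rather than raising, so a whole corpus can be
audited in one pass; structural corruption (dangling references) is the
only thing that raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .model import EntityAnn, FrameAnn, QuestionDoc

__all__ = [
    "SCHEME_NAMES",
    "SchemeDefinition",
    "Violation",
    "load_scheme",
    "validate_entity",
    "validate_frame",
    "validate_question",
    "map_question_type",
    "EMAIL_TO_WEB_TYPE_MAP",
]

SCHEME_NAMES = ("chqa-email", "chqa-web")

#: Question-type consolidations applied when moving from the email scheme
#: to the simplified web scheme.  Types absent from this map carry over
#: under their own name.
EMAIL_TO_WEB_TYPE_MAP: Mapping[str, str] = {
    "COMPLICATION": "COMPLICATION",
    "LONG_TERM_EFFECT": "COMPLICATION",
    "OVERDOSE": "COMPLICATION",
    "SIDE_EFFECT": "COMPLICATION",
    "PERSON_ORGANIZATION": "PERSON_ORGANIZATION",
    "SUPPORT_GROUP": "PERSON_ORGANIZATION",
    "FREQUENCY": "SUSCEPTIBILITY",
    "INHERITANCE": "SUSCEPTIBILITY",
    "SUSCEPTIBILITY": "SUSCEPTIBILITY",
    "DOSAGE": "USAGE",
    "STORAGE_DISPOSAL": "USAGE",
    "TAPERING": "USAGE",
    "USAGE": "USAGE",
    "EFFECT": "ASSOCIATION",
}


@dataclass(frozen=True)
class Violation:
    """One breached annotation-scheme rule on one annotation."""

    code: str  # unknown-category | unknown-type | theme-type | theme-cardinality
    #            | missing-topic | nested-entity | unknown-role | unknown-attribute
    target_id: str
    message: str

    _CODES = frozenset(
        {
            "unknown-category",
            "unknown-type",
            "theme-type",
            "theme-cardinality",
            "missing-topic",
            "nested-entity",
            "unknown-role",
            "unknown-attribute",
        }
    )

    def __post_init__(self) -> None:
        if self.code not in self._CODES:
            raise ValueError(f"unknown violation code {self.code!r}")


@dataclass(frozen=True)
class SchemeDefinition:
    """Inventories and structural constraints for one corpus part."""

    name: str
    entity_categories: frozenset[str]
    question_types: frozenset[str]
    roles: frozenset[str]
    theme_restrictions: Mapping[str, frozenset[str]]
    theme_cardinality: Mapping[str, tuple[int, int | None]]
    frame_attributes: frozenset[str]
    topic_required: bool
    nested_entities_allowed: bool

    def __post_init__(self) -> None:
        unknown = set(self.theme_restrictions) | set(self.theme_cardinality)
        unknown -= set(self.question_types)
        if unknown:
            raise ValueError(
                f"theme constraints reference unknown question types: {sorted(unknown)}"
            )

    def theme_bounds(self, qtype: str) -> tuple[int, int | None]:
        """THEME cardinality for a question type; default is exactly one."""
        return self.theme_cardinality.get(qtype, (1, 1))

    def allowed_theme_categories(self, qtype: str) -> frozenset[str]:
        """Allowed THEME entity categories; empty set means unrestricted."""
        return self.theme_restrictions.get(qtype, frozenset())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "entity_categories": sorted(self.entity_categories),
            "question_types": sorted(self.question_types),
            "roles": sorted(self.roles),
            "frame_attributes": sorted(self.frame_attributes),
            "theme_restrictions": {
                k: sorted(v) for k, v in sorted(self.theme_restrictions.items())
            },
            "theme_cardinality": {
                k: [v[0], v[1]] for k, v in sorted(self.theme_cardinality.items())
            },
            "topic_required": self.topic_required,
            "nested_entities_allowed": self.nested_entities_allowed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SchemeDefinition":
        return cls(
            name=data["name"],
            entity_categories=frozenset(data["entity_categories"]),
            question_types=frozenset(data["question_types"]),
            roles=frozenset(data["roles"]),
            theme_restrictions={
                k: frozenset(v) for k, v in (data.get("theme_restrictions") or {}).items()
            },
            theme_cardinality={
                k: (int(v[0]), None if v[1] is None else int(v[1]))
                for k, v in (data.get("theme_cardinality") or {}).items()
            },
            frame_attributes=frozenset(data.get("frame_attributes") or ()),
            topic_required=bool(data["topic_required"]),
            nested_entities_allowed=bool(data["nested_entities_allowed"]),
        )


def load_scheme(name: str) -> SchemeDefinition:
    """Load a shipped scheme definition by identifier.

    Parameters
    ----------
    name
        ``"chqa-email"`` or ``"chqa-web"``.

    Raises
    ------
    ValueError
        For an unknown scheme identifier, naming the valid ones.
    """
    if name not in SCHEME_NAMES:
        raise ValueError(
            f"unknown scheme {name!r}; valid identifiers: {', '.join(SCHEME_NAMES)}"
        )
    ref = resources.files("chqakit.schemes").joinpath(f"{name}.yaml")
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return SchemeDefinition.from_dict(data)


def validate_entity(
    entity: EntityAnn,
    scheme: SchemeDefinition,
    others: Sequence[EntityAnn] = (),
) -> list[Violation]:
    """Check one entity against the scheme.

    ``others`` supplies sibling entities of the same document so nesting can
    be detected when the scheme forbids it (an entity is nested when every
    one of its fragments lies inside some fragment of another entity).
    """
    violations: list[Violation] = []
    if entity.category not in scheme.entity_categories:
        violations.append(
            Violation(
                "unknown-category",
                entity.id,
                f"entity category {entity.category!r} is not in scheme {scheme.name}",
            )
        )
    if not scheme.nested_entities_allowed:
        for other in others:
            if other.id == entity.id:
                continue
            if _nested_within(entity, other):
                violations.append(
                    Violation(
                        "nested-entity",
                        entity.id,
                        f"entity {entity.id} is nested inside {other.id} "
                        f"but scheme {scheme.name} forbids nested entities",
                    )
                )
                break
    return violations


def _nested_within(inner: EntityAnn, outer: EntityAnn) -> bool:
    if inner.key == outer.key:
        return False
    return all(
        any(o.start <= i.start and i.end <= o.end for o in outer.mention.spans)
        for i in inner.mention.spans
    )


def validate_frame(
    frame: FrameAnn,
    entities: Sequence[EntityAnn],
    scheme: SchemeDefinition,
    qtype: str | None = None,
    doc: QuestionDoc | None = None,
) -> list[Violation]:
    """Check one frame's type, THEME restrictions/cardinality, roles, attributes.

    The frame's question type is inherited from its trigger; pass it as
    ``qtype`` or supply the owning ``doc`` for lookup.  A dangling argument
    reference is structural corruption and raises instead of producing a
    :class:`Violation`.
    """
    if qtype is None:
        if doc is None:
            raise ValueError("either qtype or doc must be supplied")
        qtype = doc.frame_qtype(frame)
    by_id = {e.id: e for e in entities}
    for role, eid in frame.args:
        if eid not in by_id:
            raise KeyError(f"frame {frame.id!r} argument {role}:{eid} does not resolve")

    violations: list[Violation] = []
    if qtype not in scheme.question_types:
        violations.append(
            Violation(
                "unknown-type",
                frame.id,
                f"question type {qtype!r} is not in scheme {scheme.name}",
            )
        )
        return violations  # theme rules are keyed by type; nothing more to check

    themes = [by_id[eid] for eid in frame.theme_refs]
    lo, hi = scheme.theme_bounds(qtype)
    if len(themes) < lo or (hi is not None and len(themes) > hi):
        bound = f"at least {lo}" if hi is None else (f"exactly {lo}" if lo == hi else f"{lo}..{hi}")
        violations.append(
            Violation(
                "theme-cardinality",
                frame.id,
                f"{qtype} frame has {len(themes)} THEME argument(s), expected {bound}",
            )
        )
    allowed = scheme.allowed_theme_categories(qtype)
    if allowed:
        for ent in themes:
            if ent.category not in allowed:
                violations.append(
                    Violation(
                        "theme-type",
                        frame.id,
                        f"THEME {ent.id} of category {ent.category} not allowed "
                        f"for {qtype} (allowed: {', '.join(sorted(allowed))})",
                    )
                )
    for role, _ in frame.args:
        if role not in scheme.roles:
            violations.append(
                Violation(
                    "unknown-role",
                    frame.id,
                    f"role {role!r} is not in scheme {scheme.name}",
                )
            )
    for attr in frame.attributes:
        if attr not in scheme.frame_attributes:
            violations.append(
                Violation(
                    "unknown-attribute",
                    frame.id,
                    f"frame attribute {attr!r} is not in scheme {scheme.name}",
                )
            )
    return violations


def validate_question(doc: QuestionDoc, scheme: SchemeDefinition) -> list[Violation]:
    """Validate every layer of one document against the scheme.

    Questions carrying an exclusion label (NOT_QUESTION, NOT_ANSWERABLE,
    DUPLICATE) are exempt from semantic validation: they are excluded from
    the corpus counts, so structural checks would be vacuous.
    """
    if doc.is_excluded:
        return []
    violations: list[Violation] = []
    for entity in doc.entities:
        violations.extend(validate_entity(entity, scheme, others=doc.entities))
    for frame in doc.frames:
        violations.extend(
            validate_frame(frame, doc.entities, scheme, qtype=doc.frame_qtype(frame))
        )
    for trigger in doc.triggers:
        if trigger.qtype not in scheme.question_types:
            violations.append(
                Violation(
                    "unknown-type",
                    trigger.id,
                    f"question type {trigger.qtype!r} is not in scheme {scheme.name}",
                )
            )
    if scheme.topic_required and not doc.topics():
        violations.append(
            Violation(
                "missing-topic",
                doc.doc_id,
                "every legitimate question must carry at least one topic entity",
            )
        )
    return violations


def map_question_type(qtype: str, source: SchemeDefinition, target: SchemeDefinition) -> str:
    """Translate a question type between the email and web schemes.

    Email → web applies the printed consolidations (e.g. DOSAGE → USAGE,
    EFFECT → ASSOCIATION); types shared by both schemes map to themselves.
    Web-only types (DIAGNOSE_ME, TIME) have no email counterpart and raise.
    """
    if qtype not in source.question_types:
        raise ValueError(f"{qtype!r} is not a question type of scheme {source.name}")
    if source.name == target.name:
        return qtype
    if source.name == "chqa-email" and target.name == "chqa-web":
        mapped = EMAIL_TO_WEB_TYPE_MAP.get(qtype, qtype)
        if mapped not in target.question_types:  # pragma: no cover - inventory guard
            raise ValueError(f"mapped type {mapped!r} missing from {target.name}")
        return mapped
    if source.name == "chqa-web" and target.name == "chqa-email":
        if qtype == "ASSOCIATION":
            return "EFFECT"
        if qtype in target.question_types:
            return qtype
        raise ValueError(f"web question type {qtype!r} has no counterpart in chqa-email")
    raise ValueError(f"no mapping between schemes {source.name} and {target.name}")
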