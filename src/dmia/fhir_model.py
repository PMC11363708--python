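"""Domain model and readers/writers for the four FHIR R4 profiles the engine exchanges.

The interview engine speaks four constrained FHIR R4 resources, all as JSON:

* ``Questionnaire`` (SDC base questionnaire) — content and structure of the
  medical interview: ordered items, answer options, ``enableWhen`` branching.
* ``Patient`` — full name and date of birth, used for on-device authentication.
* ``Task`` (SDC task) — a patient plus a canonical reference to the
  questionnaire to administer, with a small status lifecycle.
* ``QuestionnaireResponse`` — the answers collected by a completed interview.

Profile conformance is enforced *structurally* against the invariants written
into the domain types below; this module is not a generic StructureDefinition
validator and performs no terminology binding.  All validation routines return
a complete list of :class:`ProfileViolation` values rather than stopping at the
first problem; parse entry points raise :class:`ProfileValidationError`
carrying that list when the document cannot be accepted.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

__all__ = [
    "SINGLE_CHOICE",
    "MULTIPLE_CHOICE",
    "FREE_TEXT",
    "DISPLAY",
    "ITEM_TYPES",
    "AnswerOption",
    "EnableCondition",
    "QuestionItem",
    "QuestionnaireDef",
    "PatientIdentity",
    "TaskDef",
    "AnswerValue",
    "ResponseDoc",
    "ProfileViolation",
    "ParseError",
    "ProfileValidationError",
    "parse_questionnaire",
    "questionnaire_to_json",
    "parse_task",
    "task_to_json",
    "parse_response",
    "response_to_json",
    "serialize_response",
    "validate",
    "validate_questionnaire",
    "validate_response",
    "evaluate_enabled",
]

# ---------------------------------------------------------------------------
# Item types and operators
# ---------------------------------------------------------------------------

SINGLE_CHOICE = "single-choice"
MULTIPLE_CHOICE = "multiple-choice"
FREE_TEXT = "free-text"
DISPLAY = "display"
ITEM_TYPES = (SINGLE_CHOICE, MULTIPLE_CHOICE, FREE_TEXT, DISPLAY)

#: enableWhen operators supported by the engine.  The interview flow is driven
#: purely by coded answers to choice questions, so only value equality tests
#: and an "has been answered" test are needed.
OPERATORS = ("equals", "not-equals", "answered")

_FHIR_OP = {"equals": "=", "not-equals": "!=", "answered": "exists"}
_FHIR_OP_INV = {v: k for k, v in _FHIR_OP.items()}

# FHIR item.type strings accepted for each domain item type.
_FHIR_TYPE_FOR = {
    SINGLE_CHOICE: "choice",
    MULTIPLE_CHOICE: "choice",
    FREE_TEXT: "string",
    DISPLAY: "display",
}
_TEXT_FHIR_TYPES = {"string", "text"}


class ParseError(ValueError):
    """Raised when a document is not syntactically usable (bad JSON, wrong resourceType)."""


@dataclass(frozen=True)
class ProfileViolation:
    """One violated structural constraint, addressed by a JSON-ish path."""

    path: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: [{self.rule}] {self.message}"


class ProfileValidationError(ValueError):
    """A resource failed structural validation; carries every violation found."""

    def __init__(self, violations: list[ProfileViolation]):
        self.violations = list(violations)
        super().__init__(
            "; ".join(str(v) for v in self.violations) or "validation failed"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnswerOption:
    code: str
    display: str = ""


@dataclass(frozen=True)
class EnableCondition:
    """Visibility rule: show the item only if the source item's answer passes the test.

    ``value`` is the coded answer compared against and must be absent exactly
    when the operator is ``answered``.
    """

    source_link_id: str
    operator: str
    value: str | None = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown enableWhen operator {self.operator!r}")
        if (self.value is None) != (self.operator == "answered"):
            raise ValueError(
                "value must be present iff operator is not 'answered'"
            )


@dataclass(frozen=True)
class QuestionItem:
    link_id: str
    text: str
    item_type: str
    options: tuple[AnswerOption, ...] = ()
    enable_conditions: tuple[EnableCondition, ...] = ()
    enable_behavior: str = "all"  # "all" | "any"

    @property
    def is_choice(self) -> bool:
        return self.item_type in (SINGLE_CHOICE, MULTIPLE_CHOICE)

    @property
    def answerable(self) -> bool:
        return self.item_type != DISPLAY

    def option_codes(self) -> set[str]:
        return {o.code for o in self.options}


@dataclass(frozen=True)
class QuestionnaireDef:
    canonical_url: str
    title: str
    items: tuple[QuestionItem, ...] = ()

    def __post_init__(self) -> None:
        violations = validate_questionnaire(self)
        hard = [v for v in violations if v.rule != "enable-behavior-implicit"]
        if hard:
            raise ProfileValidationError(hard)

    @property
    def answerable_items(self) -> tuple[QuestionItem, ...]:
        return tuple(i for i in self.items if i.answerable)

    def item(self, link_id: str) -> QuestionItem:
        for it in self.items:
            if it.link_id == link_id:
                return it
        raise KeyError(link_id)

    def __contains__(self, link_id: str) -> bool:
        return any(i.link_id == link_id for i in self.items)


@dataclass(frozen=True)
class PatientIdentity:
    """The two data elements used for authentication: full name and birth date."""

    full_name: str
    birth_date: _dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.birth_date, _dt.date):
            object.__setattr__(
                self, "birth_date", _dt.date.fromisoformat(str(self.birth_date))
            )


_TASK_STATUSES = ("requested", "in-progress", "completed", "suspended")
_TASK_TRANSITIONS = {
    "requested": {"in-progress"},
    "in-progress": {"completed", "suspended"},
    "completed": set(),
    "suspended": set(),
}


@dataclass
class TaskDef:
    """An order to administer one questionnaire to one patient."""

    patient: PatientIdentity
    questionnaire_url: str
    status: str = "requested"

    def __post_init__(self) -> None:
        if self.status not in _TASK_STATUSES:
            raise ValueError(f"unknown task status {self.status!r}")

    def transition(self, new_status: str) -> None:
        if new_status not in _TASK_TRANSITIONS.get(self.status, set()):
            raise ValueError(
                f"illegal task transition {self.status!r} -> {new_status!r}"
            )
        self.status = new_status


@dataclass(frozen=True)
class AnswerValue:
    """One recorded answer: either a coded option or verbatim free text."""

    kind: str  # "coded" | "text"
    value: str

    def __post_init__(self) -> None:
        if self.kind not in ("coded", "text"):
            raise ValueError(f"unknown answer kind {self.kind!r}")


@dataclass(frozen=True)
class ResponseDoc:
    """A completed questionnaire response: link_id -> ordered answer values."""

    questionnaire_url: str
    answers: Mapping[str, tuple[AnswerValue, ...]]
    authored: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "answers",
            {k: tuple(v) for k, v in self.answers.items()},
        )


# ---------------------------------------------------------------------------
# enableWhen evaluation (shared with the interview engine)
# ---------------------------------------------------------------------------


def evaluate_enabled(
    item: QuestionItem, answers: Mapping[str, Iterable[AnswerValue]]
) -> bool:
    """True iff *item* is visible given the coded answers recorded so far.

    A condition on an unanswered source evaluates false, so follow-up items
    are never shown before their source question.  ``equals`` passes when any
    recorded answer of the source equals the value (FHIR any-answer
    semantics); ``not-equals`` passes when the source was answered and no
    recorded answer equals the value.
    """
    if not item.enable_conditions:
        return True
    results = []
    for cond in item.enable_conditions:
        vals = [a.value for a in answers.get(cond.source_link_id, ())]
        if cond.operator == "answered":
            results.append(bool(vals))
        elif not vals:
            results.append(False)
        elif cond.operator == "equals":
            results.append(cond.value in vals)
        else:  # not-equals
            results.append(cond.value not in vals)
    return any(results) if item.enable_behavior == "any" else all(results)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_questionnaire(q: QuestionnaireDef | Iterable[QuestionItem]) -> list[ProfileViolation]:
    """Check every structural invariant of a questionnaire; return all violations."""
    items = tuple(q.items) if isinstance(q, QuestionnaireDef) else tuple(q)
    out: list[ProfileViolation] = []
    seen: dict[str, int] = {}
    earlier: dict[str, QuestionItem] = {}  # first occurrence of each prior linkId
    for idx, it in enumerate(items):
        path = f"item[{idx}](linkId={it.link_id})"
        if it.link_id in seen:
            out.append(
                ProfileViolation(path, "duplicate-link-id",
                                 f"linkId {it.link_id!r} already used at item[{seen[it.link_id]}]")
            )
        if it.item_type not in ITEM_TYPES:
            out.append(ProfileViolation(path, "unknown-item-type",
                                        f"unknown item type {it.item_type!r}"))
        if it.is_choice and len(it.options) < 2:
            out.append(ProfileViolation(path, "choice-needs-options",
                                        "choice items need at least 2 answer options"))
        if not it.is_choice and it.options:
            out.append(ProfileViolation(path, "options-on-non-choice",
                                        f"{it.item_type} items must not carry answer options"))
        codes = [o.code for o in it.options]
        if len(codes) != len(set(codes)):
            out.append(ProfileViolation(path, "duplicate-option-code",
                                        "answer option codes must be unique"))
        for c_idx, cond in enumerate(it.enable_conditions):
            cpath = f"{path}.enableWhen[{c_idx}]"
            src = earlier.get(cond.source_link_id)
            if src is None:
                out.append(ProfileViolation(
                    cpath, "dangling-enable-reference",
                    f"enableWhen references {cond.source_link_id!r}, which does not "
                    "occur earlier in document order"))
            elif cond.operator != "answered":
                if not src.is_choice:
                    out.append(ProfileViolation(
                        cpath, "enable-source-not-choice",
                        "value-comparing conditions must reference a choice item"))
                elif cond.value not in src.option_codes():
                    out.append(ProfileViolation(
                        cpath, "enable-value-not-an-option",
                        f"value {cond.value!r} is not an option of {cond.source_link_id!r}"))
        if it.enable_behavior not in ("all", "any"):
            out.append(ProfileViolation(path, "unknown-enable-behavior",
                                        f"enableBehavior must be all|any, got {it.enable_behavior!r}"))
        seen.setdefault(it.link_id, idx)
        earlier.setdefault(it.link_id, it)
    return out


def validate_response(
    doc: ResponseDoc, questionnaire: QuestionnaireDef
) -> list[ProfileViolation]:
    """Check a response against its questionnaire: known items, cardinality,
    coded values among options, and only-enabled-items-present."""
    out: list[ProfileViolation] = []
    if doc.questionnaire_url != questionnaire.canonical_url:
        out.append(ProfileViolation("questionnaire", "questionnaire-url-mismatch",
                                    f"response targets {doc.questionnaire_url!r}, "
                                    f"expected {questionnaire.canonical_url!r}"))
    for link_id, values in doc.answers.items():
        path = f"item(linkId={link_id})"
        if link_id not in questionnaire:
            out.append(ProfileViolation(path, "unknown-link-id",
                                        f"no item {link_id!r} in questionnaire"))
            continue
        item = questionnaire.item(link_id)
        if not item.answerable:
            out.append(ProfileViolation(path, "answer-on-display-item",
                                        "display items take no answers"))
            continue
        if not values:
            out.append(ProfileViolation(path, "empty-answer", "item present without answers"))
        if item.item_type == SINGLE_CHOICE and len(values) != 1:
            out.append(ProfileViolation(path, "single-choice-cardinality",
                                        f"single-choice items take exactly 1 answer, got {len(values)}"))
        if item.item_type == FREE_TEXT and len(values) != 1:
            out.append(ProfileViolation(path, "free-text-cardinality",
                                        f"free-text items take exactly 1 answer, got {len(values)}"))
        for v in values:
            if item.is_choice:
                if v.kind != "coded":
                    out.append(ProfileViolation(path, "answer-kind-mismatch",
                                                "choice items take coded answers"))
                elif v.value not in item.option_codes():
                    out.append(ProfileViolation(path, "code-not-an-option",
                                                f"code {v.value!r} is not an option"))
            elif v.kind != "text":
                out.append(ProfileViolation(path, "answer-kind-mismatch",
                                            "free-text items take text answers"))
        if not evaluate_enabled(item, doc.answers):
            out.append(ProfileViolation(path, "answer-on-disabled-item",
                                        "item is disabled by its enable conditions"))
    return out


def validate(resource: Any, kind: str, questionnaire: QuestionnaireDef | None = None
             ) -> list[ProfileViolation]:
    """Dispatching validator; returns all violations, never raises on content."""
    if kind == "questionnaire":
        return validate_questionnaire(resource)
    if kind == "response":
        if questionnaire is None:
            raise ValueError("response validation needs the questionnaire")
        return validate_response(resource, questionnaire)
    if kind == "task":
        out = []
        if resource.status not in _TASK_STATUSES:
            out.append(ProfileViolation("status", "unknown-task-status",
                                        f"unknown status {resource.status!r}"))
        if not resource.questionnaire_url:
            out.append(ProfileViolation("focus", "missing-questionnaire-reference",
                                        "task carries no questionnaire reference"))
        if resource.patient.birth_date > _dt.date.today():
            out.append(ProfileViolation("patient.birthDate", "birth-date-in-future",
                                        "birth date must be a past date"))
        return out
    raise ValueError(f"unknown resource kind {kind!r}")


# ---------------------------------------------------------------------------
# JSON readers
# ---------------------------------------------------------------------------


def _load(document: str | bytes | Mapping[str, Any], expected_type: str) -> dict:
    if isinstance(document, (str, bytes)):
        try:
            doc = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON: {exc}") from exc
    else:
        doc = dict(document)
    if not isinstance(doc, dict) or doc.get("resourceType") != expected_type:
        raise ParseError(
            f"expected resourceType {expected_type!r}, "
            f"got {doc.get('resourceType') if isinstance(doc, dict) else type(doc).__name__!r}"
        )
    return doc


def _item_from_json(raw: Mapping[str, Any], idx: int,
                    violations: list[ProfileViolation]) -> QuestionItem | None:
    path = f"item[{idx}]"
    link_id = raw.get("linkId")
    if not link_id:
        violations.append(ProfileViolation(path, "missing-link-id", "item has no linkId"))
        return None
    ftype = raw.get("type")
    if ftype == "choice":
        item_type = MULTIPLE_CHOICE if raw.get("repeats") else SINGLE_CHOICE
    elif ftype in _TEXT_FHIR_TYPES:
        item_type = FREE_TEXT
    elif ftype == DISPLAY:
        item_type = DISPLAY
    else:
        violations.append(ProfileViolation(path, "unknown-item-type",
                                           f"unsupported item type {ftype!r}"))
        return None
    options = []
    for opt in raw.get("answerOption", ()):
        coding = opt.get("valueCoding", {})
        code = coding.get("code", opt.get("valueString"))
        if code is None:
            violations.append(ProfileViolation(path, "option-without-code",
                                               "answerOption carries no code"))
            continue
        options.append(AnswerOption(code=str(code), display=coding.get("display", "")))
    conditions = []
    for ew in raw.get("enableWhen", ()):
        op = _FHIR_OP_INV.get(ew.get("operator", ""))
        if op is None:
            violations.append(ProfileViolation(path, "unknown-operator",
                                               f"unsupported enableWhen operator {ew.get('operator')!r}"))
            continue
        if op == "answered":
            value = None
        else:
            value = (ew.get("answerCoding") or {}).get("code", ew.get("answerString"))
            if value is None:
                violations.append(ProfileViolation(path, "condition-without-value",
                                                   "enableWhen comparison carries no answer value"))
                continue
        conditions.append(EnableCondition(ew["question"], op, value))
    behavior = raw.get("enableBehavior")
    if behavior is None:
        behavior = "all"
        if len(conditions) > 1:
            # FHIR requires enableBehavior whenever >1 condition; accept but flag.
            violations.append(ProfileViolation(path, "enable-behavior-implicit",
                                               "enableBehavior absent with multiple "
                                               "conditions; defaulting to 'all'"))
    return QuestionItem(
        link_id=str(link_id),
        text=raw.get("text", ""),
        item_type=item_type,
        options=tuple(options),
        enable_conditions=tuple(conditions),
        enable_behavior=behavior,
    )


def parse_questionnaire(document: str | bytes | Mapping[str, Any]) -> QuestionnaireDef:
    """Parse a FHIR R4 Questionnaire JSON document into a :class:`QuestionnaireDef`.

    Raises :class:`ParseError` on malformed JSON and
    :class:`ProfileValidationError` (listing *all* problems) when the document
    violates the structural profile.
    """
    doc = _load(document, "Questionnaire")
    violations: list[ProfileViolation] = []
    items = []
    for idx, raw in enumerate(doc.get("item", ())):
        it = _item_from_json(raw, idx, violations)
        if it is not None:
            items.append(it)
    violations.extend(validate_questionnaire(items))
    hard = [v for v in violations if v.rule != "enable-behavior-implicit"]
    if hard:
        raise ProfileValidationError(hard)
    return QuestionnaireDef(
        canonical_url=doc.get("url", ""),
        title=doc.get("title", ""),
        items=tuple(items),
    )


def parse_task(document: str | bytes | Mapping[str, Any]) -> TaskDef:
    """Parse a FHIR R4 Task with a contained Patient and a questionnaire reference."""
    doc = _load(document, "Task")
    violations: list[ProfileViolation] = []
    url = (doc.get("focus") or {}).get("reference", "")
    if not url:
        for inp in doc.get("input", ()):
            if "valueCanonical" in inp:
                url = inp["valueCanonical"]
                break
    if not url:
        violations.append(ProfileViolation("focus", "missing-questionnaire-reference",
                                           "no questionnaire URL on task"))
    patient = None
    for contained in doc.get("contained", ()):
        if contained.get("resourceType") == "Patient":
            patient = _patient_from_json(contained, violations)
            break
    if patient is None:
        violations.append(ProfileViolation("contained", "missing-patient",
                                           "task carries no contained Patient"))
    if violations:
        raise ProfileValidationError(violations)
    status = doc.get("status", "requested")
    try:
        return TaskDef(patient=patient, questionnaire_url=url, status=status)
    except ValueError as exc:
        raise ProfileValidationError(
            [ProfileViolation("status", "unknown-task-status", str(exc))]
        ) from exc


def _patient_from_json(raw: Mapping[str, Any],
                       violations: list[ProfileViolation]) -> PatientIdentity | None:
    names = raw.get("name") or []
    full = ""
    if names:
        n0 = names[0]
        full = n0.get("text") or " ".join(
            list(n0.get("given", ())) + ([n0["family"]] if n0.get("family") else [])
        )
    if not full:
        violations.append(ProfileViolation("name", "missing-name", "patient has no usable name"))
    bd = raw.get("birthDate")
    if not bd:
        violations.append(ProfileViolation("birthDate", "missing-birth-date",
                                           "patient has no birthDate"))
    if not full or not bd:
        return None
    try:
        birth = _dt.date.fromisoformat(bd)
    except ValueError:
        violations.append(ProfileViolation("birthDate", "bad-birth-date",
                                           f"not an ISO-8601 date: {bd!r}"))
        return None
    return PatientIdentity(full_name=full, birth_date=birth)


def parse_response(document: str | bytes | Mapping[str, Any]) -> ResponseDoc:
    """Parse a FHIR R4 QuestionnaireResponse into a :class:`ResponseDoc`."""
    doc = _load(document, "QuestionnaireResponse")
    answers: dict[str, tuple[AnswerValue, ...]] = {}
    for raw in doc.get("item", ()):
        vals = []
        for ans in raw.get("answer", ()):
            if "valueCoding" in ans:
                vals.append(AnswerValue("coded", str(ans["valueCoding"].get("code", ""))))
            elif "valueString" in ans:
                vals.append(AnswerValue("text", ans["valueString"]))
        answers[raw["linkId"]] = tuple(vals)
    return ResponseDoc(
        questionnaire_url=doc.get("questionnaire", ""),
        answers=answers,
        authored=doc.get("authored", ""),
    )


# ---------------------------------------------------------------------------
# JSON writers
# ---------------------------------------------------------------------------


def questionnaire_to_json(q: QuestionnaireDef) -> dict:
    items = []
    for it in q.items:
        raw: dict[str, Any] = {
            "linkId": it.link_id,
            "text": it.text,
            "type": _FHIR_TYPE_FOR[it.item_type],
        }
        if it.item_type == MULTIPLE_CHOICE:
            raw["repeats"] = True
        if it.options:
            raw["answerOption"] = [
                {"valueCoding": {"code": o.code, "display": o.display}}
                for o in it.options
            ]
        if it.enable_conditions:
            raw["enableWhen"] = [
                {
                    "question": c.source_link_id,
                    "operator": _FHIR_OP[c.operator],
                    **(
                        {"answerBoolean": True}
                        if c.operator == "answered"
                        else {"answerCoding": {"code": c.value}}
                    ),
                }
                for c in it.enable_conditions
            ]
            raw["enableBehavior"] = it.enable_behavior
        items.append(raw)
    return {
        "resourceType": "Questionnaire",
        "url": q.canonical_url,
        "title": q.title,
        "status": "active",
        "item": items,
    }


def task_to_json(task: TaskDef) -> dict:
    given, _, family = task.patient.full_name.partition(" ")
    return {
        "resourceType": "Task",
        "status": task.status,
        "intent": "order",
        "focus": {"reference": task.questionnaire_url},
        "for": {"reference": "#patient"},
        "contained": [
            {
                "resourceType": "Patient",
                "id": "patient",
                "name": [
                    {
                        "text": task.patient.full_name,
                        "given": [given] if given else [],
                        **({"family": family} if family else {}),
                    }
                ],
                "birthDate": task.patient.birth_date.isoformat(),
            }
        ],
    }


def response_to_json(doc: ResponseDoc, questionnaire: QuestionnaireDef | None = None) -> dict:
    items = []
    for link_id, values in doc.answers.items():
        text = ""
        if questionnaire is not None and link_id in questionnaire:
            text = questionnaire.item(link_id).text
        answers = []
        for v in values:
            if v.kind == "coded":
                answers.append({"valueCoding": {"code": v.value}})
            else:
                answers.append({"valueString": v.value})
        items.append({"linkId": link_id, **({"text": text} if text else {}), "answer": answers})
    return {
        "resourceType": "QuestionnaireResponse",
        "questionnaire": doc.questionnaire_url,
        "status": "completed",
        **({"authored": doc.authored} if doc.authored else {}),
        "item": items,
    }


def serialize_response(session: Any) -> dict:
    """Populate the QuestionnaireResponse JSON for a submitted interview session.

    Only enabled, answered items appear.  Raises a state error when the
    session has not been submitted yet.
    """
    if getattr(session, "phase", None) != "submitted":
        raise ProfileValidationError(
            [ProfileViolation("session.phase", "not-submitted",
                              "only submitted sessions can be serialized")]
        )
    doc = ResponseDoc(
        questionnaire_url=session.questionnaire.canonical_url,
        answers=dict(session.answers),
        authored=session.authored,
    )
    return response_to_json(doc, session.questionnaire)
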