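"""Three-phase dialogue state machine for the digital medical interview.

A session moves through ``onboarding -> interview -> qa -> confirmation ->
submitted``; ``suspended`` is reachable only from onboarding (failed
authentication).  During onboarding the patient authenticates with full name
and birth date against the task's Patient resource.  The interview phase walks
the questionnaire in document order, showing each item only when its
``enableWhen`` conditions hold against the answers recorded so far — e.g.
pregnancy questions are skipped for patients who state they are male.  All
posed questions are mandatory and free text is stored verbatim, never
interpreted.  The Q&A phase forwards free-text queries to a retrieval
knowledge base; the user ends it explicitly.  A confirmation summary is
read-only; submission populates the QuestionnaireResponse and a JSON-lines
transcript log.
"""

from __future__ import annotations

import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from . import fhir_model as fm
from .fhir_model import (
    AnswerValue,
    PatientIdentity,
    QuestionItem,
    QuestionnaireDef,
    ResponseDoc,
    TaskDef,
)
from .qa_module import KnowledgeBase, QueryResult, UnansweredStore, match

__all__ = [
    "PHASES",
    "StateError",
    "AnswerError",
    "Clock",
    "TranscriptTurn",
    "SummaryView",
    "InterviewSession",
    "start_session",
    "authenticate",
    "normalize_name",
    "next_item",
    "is_enabled",
    "record_answer",
    "ask_question",
    "end_qa",
    "build_summary",
    "submit",
    "run_scripted_session",
]

PHASES = ("onboarding", "interview", "qa", "confirmation", "submitted", "suspended")

WELCOME_MESSAGE = (
    "Welcome! I will guide you through a short medical interview before your "
    "examination. Your answers are stored locally on this device and handled "
    "confidentially; they are shared only with the treating clinical team."
)
AUTH_PROMPT = "Please identify yourself with your full name and your date of birth."
SUSPEND_MESSAGE = (
    "I could not verify your identity. Please reach out to the hospital staff for help."
)
QA_INTRO = "You may now ask me questions about the upcoming examination."


class StateError(RuntimeError):
    """An operation was invoked in a phase that does not allow it."""


class AnswerError(ValueError):
    """A recorded answer violates the posed item's contract."""

    def __init__(self, kind: str, message: str):
        self.kind = kind  # mandatory | invalid-option | cardinality | kind
        super().__init__(message)


class Clock:
    """Deterministic monotonic clock; inject for reproducible transcripts."""

    def __init__(self, start: float = 0.0, step: float = 1.0):
        self._t = start
        self._step = step

    def __call__(self) -> float:
        self._t += self._step
        return self._t


@dataclass(frozen=True)
class TranscriptTurn:
    speaker: str  # "agent" | "user"
    text: str
    timestamp: float
    item_ref: str | None = None

    def to_json(self) -> dict:
        return {
            "speaker": self.speaker,
            "text": self.text,
            "timestamp": self.timestamp,
            "item_ref": self.item_ref,
        }


@dataclass(frozen=True)
class SummaryView:
    """Read-only confirmation page: (question text, rendered answer text) pairs."""

    entries: tuple[tuple[str, str], ...]


@dataclass
class InterviewSession:
    task: TaskDef
    questionnaire: QuestionnaireDef
    phase: str = "onboarding"
    answers: dict[str, tuple[AnswerValue, ...]] = field(default_factory=dict)
    qa_turns: list[tuple[str, QueryResult]] = field(default_factory=list)
    transcript: list[TranscriptTurn] = field(default_factory=list)
    auth_attempts_used: int = 0
    max_auth_attempts: int = 1
    authored: str = ""
    clock: Clock = field(default_factory=Clock)
    unanswered_store: UnansweredStore = field(default_factory=UnansweredStore)
    _pending_item: str | None = None
    _displayed: set[str] = field(default_factory=set)

    # -- transcript helpers -------------------------------------------------
    def _say(self, text: str, item_ref: str | None = None) -> None:
        self.transcript.append(
            TranscriptTurn("agent", text, self.clock(), item_ref)
        )

    def _hear(self, text: str, item_ref: str | None = None) -> None:
        self.transcript.append(
            TranscriptTurn("user", text, self.clock(), item_ref)
        )

    def _require_phase(self, *phases: str) -> None:
        if self.phase == "suspended" and "suspended" not in phases:
            raise StateError("session is suspended; only inspection is allowed")
        if self.phase not in phases:
            raise StateError(
                f"operation requires phase {' or '.join(phases)}, session is in {self.phase}"
            )


# ---------------------------------------------------------------------------
# Onboarding
# ---------------------------------------------------------------------------


def start_session(
    task: TaskDef,
    questionnaire: QuestionnaireDef,
    *,
    max_auth_attempts: int = 1,
    clock: Clock | None = None,
) -> InterviewSession:
    """Open a session for a requested task; moves the task to in-progress.

    The first agent turns are the welcome with the data-handling notice and
    the identification prompt.
    """
    if task.status != "requested":
        raise StateError(f"task must be in status 'requested', is {task.status!r}")
    if task.questionnaire_url != questionnaire.canonical_url:
        raise StateError(
            f"task references questionnaire {task.questionnaire_url!r}, "
            f"got {questionnaire.canonical_url!r}"
        )
    task.transition("in-progress")
    session = InterviewSession(
        task=task,
        questionnaire=questionnaire,
        max_auth_attempts=max_auth_attempts,
        clock=clock or Clock(),
    )
    session._say(WELCOME_MESSAGE)
    session._say(AUTH_PROMPT)
    return session


_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)


def normalize_name(name: str) -> Counter:
    """Name comparison key: Unicode-normalized, case-folded token multiset.

    Token order is ignored so "Muster Erika" authenticates against
    "Erika Muster" — users are often unsure in which order to enter given and
    family name.
    """
    text = unicodedata.normalize("NFKC", name).casefold()
    text = _PUNCT_RE.sub(" ", text)
    return Counter(text.split())


def authenticate(session: InterviewSession, claimed: PatientIdentity) -> str:
    """Check claimed identity against the task's patient.

    Returns ``"authenticated"`` (session enters the interview), ``"retry"``
    (attempts remain) or ``"suspended"`` (attempts exhausted; the task is
    suspended and the patient directed to hospital staff).
    """
    session._require_phase("onboarding")
    session._hear(f"{claimed.full_name}, {claimed.birth_date.isoformat()}")
    session.auth_attempts_used += 1
    stored = session.task.patient
    name_ok = normalize_name(claimed.full_name) == normalize_name(stored.full_name)
    if name_ok and claimed.birth_date == stored.birth_date:
        session.phase = "interview"
        session._say("Thank you, your identity is confirmed. Let us begin.")
        return "authenticated"
    if session.auth_attempts_used >= session.max_auth_attempts:
        session.phase = "suspended"
        session.task.transition("suspended")
        session._say(SUSPEND_MESSAGE)
        return "suspended"
    session._say("I could not match this information. Please try again.")
    return "retry"


# ---------------------------------------------------------------------------
# Interview
# ---------------------------------------------------------------------------


def is_enabled(item: QuestionItem, answers: Mapping[str, Iterable[AnswerValue]]) -> bool:
    """Whether *item* may currently be asked, given the recorded answers."""
    return fm.evaluate_enabled(item, answers)


def next_item(session: InterviewSession) -> QuestionItem | None:
    """The first document-order item that is enabled and unanswered.

    Display items are spoken into the transcript and skipped (they take no
    answer).  Returns ``None`` once no item remains, after moving the session
    into the Q&A phase.
    """
    session._require_phase("interview")
    for item in session.questionnaire.items:
        if item.link_id in session.answers:
            continue
        if not is_enabled(item, session.answers):
            continue
        if item.item_type == fm.DISPLAY:
            if item.link_id not in session._displayed:
                session._displayed.add(item.link_id)
                session._say(item.text, item.link_id)
            continue
        if session._pending_item != item.link_id:
            session._pending_item = item.link_id
            session._say(item.text, item.link_id)
        return item
    session._pending_item = None
    session.phase = "qa"
    session._say(QA_INTRO)
    return None


def record_answer(
    session: InterviewSession, link_id: str, raw_answer: str | Iterable[str]
) -> InterviewSession:
    """Store the answer to the currently posed item after type checking.

    Every posed question is mandatory: an empty answer is rejected.  Coded
    answers must be among the item's options; single-choice items take exactly
    one value.  Free text is stored verbatim.
    """
    session._require_phase("interview")
    if session._pending_item != link_id:
        raise StateError(
            f"item {link_id!r} is not the currently posed item ({session._pending_item!r})"
        )
    item = session.questionnaire.item(link_id)
    if isinstance(raw_answer, str):
        raw_values = [raw_answer]
    else:
        raw_values = [str(v) for v in raw_answer]
    raw_values = [v for v in raw_values if v.strip() != ""]
    if not raw_values:
        raise AnswerError("mandatory", f"question {link_id!r} is mandatory and cannot be skipped")
    if item.item_type == fm.SINGLE_CHOICE and len(raw_values) > 1:
        raise AnswerError("cardinality",
                          f"single-choice item {link_id!r} takes exactly one answer, "
                          f"got {len(raw_values)}")
    if item.item_type == fm.FREE_TEXT and len(raw_values) > 1:
        raise AnswerError("cardinality", f"free-text item {link_id!r} takes one answer")
    if item.is_choice:
        codes = item.option_codes()
        bad = [v for v in raw_values if v not in codes]
        if bad:
            raise AnswerError("invalid-option",
                              f"answer {bad[0]!r} is not an option of {link_id!r}")
        if len(set(raw_values)) != len(raw_values):
            raise AnswerError("cardinality", f"duplicate option codes for {link_id!r}")
        values = tuple(AnswerValue("coded", v) for v in raw_values)
    else:
        values = tuple(AnswerValue("text", v) for v in raw_values)
    session.answers[link_id] = values
    session._hear("; ".join(raw_values), link_id)
    session._pending_item = None
    return session


# ---------------------------------------------------------------------------
# Q&A phase
# ---------------------------------------------------------------------------


def ask_question(
    session: InterviewSession, query: str, kb: KnowledgeBase, backend=None
) -> QueryResult:
    """Forward one free-text query to the knowledge base and record the turn."""
    session._require_phase("qa")
    session._hear(query)
    result = match(query, kb, backend=backend, store=session.unanswered_store)
    session.qa_turns.append((query, result))
    session._say(result.answer_text)
    return result


def end_qa(session: InterviewSession) -> None:
    """User-issued done signal: leave the Q&A phase for the confirmation page.

    Asking zero questions is allowed.
    """
    session._require_phase("qa")
    session.phase = "confirmation"
    session._say("Here is a summary of your answers. Please review and submit.")


# ---------------------------------------------------------------------------
# Confirmation and submission
# ---------------------------------------------------------------------------


def _render_answer(item: QuestionItem, values: tuple[AnswerValue, ...]) -> str:
    if item.is_choice:
        labels = {o.code: (o.display or o.code) for o in item.options}
        return ", ".join(labels[v.value] for v in values)
    return "; ".join(v.value for v in values)


def build_summary(session: InterviewSession) -> SummaryView:
    """Read-only confirmation page: one entry per answered item, in asked order."""
    session._require_phase("confirmation")
    entries = []
    for item in session.questionnaire.items:
        if item.link_id in session.answers:
            entries.append(
                (item.text, _render_answer(item, session.answers[item.link_id]))
            )
    return SummaryView(entries=tuple(entries))


def submit(session: InterviewSession) -> tuple[ResponseDoc, list[dict]]:
    """Submit the confirmed session.

    Populates the response document (only enabled, answered items), completes
    the task and returns the transcript log as JSON-ready dicts, one turn per
    line, covering the whole conversation including the Q&A turns.  A session
    can be submitted once.
    """
    session._require_phase("confirmation")
    session.authored = f"1970-01-01T00:00:{int(session.clock()) % 60:02d}Z"
    session.phase = "submitted"
    session.task.transition("completed")
    doc = ResponseDoc(
        questionnaire_url=session.questionnaire.canonical_url,
        answers=dict(session.answers),
        authored=session.authored,
    )
    violations = fm.validate_response(doc, session.questionnaire)
    if violations:  # engine bug if ever reached: answers are checked on entry
        raise fm.ProfileValidationError(violations)
    log = [turn.to_json() for turn in session.transcript]
    return doc, log


def transcript_log_lines(log: list[dict]) -> str:
    """Serialize a transcript log as JSON lines (one turn per line)."""
    return "\n".join(json.dumps(turn, ensure_ascii=False) for turn in log)


# ---------------------------------------------------------------------------
# Scripted, non-interactive execution
# ---------------------------------------------------------------------------


def run_scripted_session(
    task: TaskDef,
    questionnaire: QuestionnaireDef,
    script: Mapping[str, Any],
    kb: KnowledgeBase | None = None,
    backend=None,
    *,
    max_auth_attempts: int = 1,
    clock: Clock | None = None,
) -> InterviewSession:
    """Drive a full session from a scripted-session document.

    The script maps ``identity`` to {name, birth_date}, ``answers`` to
    link_id -> answer(s) and optionally ``qa_queries`` to a list of free-text
    questions.  Used by the CLI and the test-suite to run the flow
    non-interactively.
    """
    session = start_session(
        task, questionnaire, max_auth_attempts=max_auth_attempts, clock=clock
    )
    ident = script.get("identity", {})
    claimed = PatientIdentity(
        full_name=ident.get("name", task.patient.full_name),
        birth_date=ident.get("birth_date", task.patient.birth_date),
    )
    outcome = authenticate(session, claimed)
    if outcome != "authenticated":
        return session
    answers = script.get("answers", {})
    while (item := next_item(session)) is not None:
        if item.link_id not in answers:
            raise AnswerError("mandatory",
                              f"script provides no answer for posed item {item.link_id!r}")
        record_answer(session, item.link_id, answers[item.link_id])
    if kb is not None:
        for query in script.get("qa_queries", ()):
            ask_question(session, query, kb, backend=backend)
    end_qa(session)
    return session
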