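"""Deterministic synthetic fixtures: questionnaires, sessions, knowledge bases.

Everything the other modules consume can be generated here from a seed, so the
whole pipeline runs without any deposited artifact.  The default composition
mirrors the reference deployment: a 31-item interview (18 single-choice, 7
multiple-choice, 6 free-text) that always contains a gender question whose
"male" answer disables a pregnancy question, and a 33-pair examination
knowledge base.  In-KB evaluation queries are token-level paraphrases of
knowledge-base questions; out-of-KB queries draw from a vocabulary that is
disjoint by construction, so the lexical matcher scores them 0.

Generated text is synthetic German-like token strings — content realism is out
of scope; what matters is statistical structure (lengths, vocabulary overlap).
Generation is pure given (spec, seed).
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import LabeledQuery
from .fhir_model import (
    FREE_TEXT,
    MULTIPLE_CHOICE,
    SINGLE_CHOICE,
    AnswerOption,
    EnableCondition,
    PatientIdentity,
    QuestionItem,
    QuestionnaireDef,
    TaskDef,
    questionnaire_to_json,
    task_to_json,
)
from .qa_module import KnowledgeBase, QAPair, kb_to_json, tokenize

__all__ = [
    "FixtureSpec",
    "gen_questionnaire",
    "gen_task",
    "gen_scripted_session",
    "gen_kb",
    "gen_labeled_queries",
    "paraphrase",
    "write_fixture_files",
    "GENDER_LINK_ID",
    "PREGNANCY_LINK_ID",
]

GENDER_LINK_ID = "gender"
PREGNANCY_LINK_ID = "pregnancy"

DEFAULT_PATIENT = PatientIdentity("Erika Muster", _dt.date(1970, 1, 1))


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study: item composition, branching, KB and query counts.

    Defaults reproduce the reference deployment's scale: 18/7/6 interview
    items, a 33-pair knowledge base, and a labeled query set of 54 in-KB plus
    60 out-of-KB queries (the 114-query evaluation split).
    """

    seed: int = 0
    n_single: int = 18
    n_multi: int = 7
    n_free: int = 6
    branch_fraction: float = 0.2
    kb_size: int = 33
    paraphrase_strength: float = 0.2
    n_in_kb: int = 54
    n_out_kb: int = 60

    def __post_init__(self) -> None:
        if min(self.n_single, self.n_multi, self.n_free, self.kb_size,
               self.n_in_kb, self.n_out_kb) < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.branch_fraction <= 1.0
                and 0.0 <= self.paraphrase_strength <= 1.0):
            raise ValueError("fractions must be in [0, 1]")


# ---------------------------------------------------------------------------
# Synthetic German-like vocabulary
# ---------------------------------------------------------------------------

# Two onset-disjoint syllable inventories: every word starts with a consonant
# from its inventory, so the vocabularies can never collide token-for-token.
_SYLLABLES_A = [c + v for c in ("br", "d", "f", "gr", "pf", "schw", "tr", "w")
                for v in ("a", "ei", "o", "u", "en", "ie")]
_SYLLABLES_B = [c + v for c in ("kl", "l", "m", "n", "qu", "r", "st", "z")
                for v in ("a", "ei", "o", "u", "en", "ie")]


def _make_vocab(rng: random.Random, syllables: list[str], size: int) -> list[str]:
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        word = "".join(rng.choice(syllables) for _ in range(rng.randint(2, 4)))
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return vocab


def _sentence(rng: random.Random, vocab: list[str], n_tokens: int,
              terminal: str = "?") -> str:
    words = [rng.choice(vocab) for _ in range(n_tokens)]
    return " ".join(words).capitalize() + terminal


# ---------------------------------------------------------------------------
# Questionnaire generation
# ---------------------------------------------------------------------------


def gen_questionnaire(spec: FixtureSpec = FixtureSpec()) -> QuestionnaireDef:
    """A valid branching questionnaire with the spec'd item composition.

    When at least two single-choice items are requested, the first item is a
    gender question and a later pregnancy question carries the condition
    ``gender not-equals male`` — the canonical branching example.  A further
    ``branch_fraction`` share of the remaining items receives an
    equals-condition on a randomly chosen earlier choice item.  Deterministic
    for a fixed seed; the result always validates with zero violations.
    """
    total = spec.n_single + spec.n_multi + spec.n_free
    if total < 1:
        raise ValueError("questionnaire needs at least one item")
    if spec.branch_fraction > 0 and spec.n_single + spec.n_multi == 0:
        raise ValueError("branching requires at least one choice item")
    rng = random.Random(spec.seed)
    vocab = _make_vocab(rng, _SYLLABLES_A, 140)

    with_specials = spec.n_single >= 2
    types = ([SINGLE_CHOICE] * (spec.n_single - (2 if with_specials else 0))
             + [MULTIPLE_CHOICE] * spec.n_multi
             + [FREE_TEXT] * spec.n_free)
    rng.shuffle(types)

    items: list[QuestionItem] = []
    if with_specials:
        items.append(QuestionItem(
            link_id=GENDER_LINK_ID,
            text="Welches Geschlecht haben Sie?",
            item_type=SINGLE_CHOICE,
            options=(AnswerOption("male", "männlich"),
                     AnswerOption("female", "weiblich"),
                     AnswerOption("other", "divers")),
        ))
        # insert the pregnancy item somewhere after the gender item
        preg_pos = rng.randint(1, len(types)) if types else 1
        types.insert(preg_pos - 1, "pregnancy")

    counter = 0
    for t in types:
        counter += 1
        if t == "pregnancy":
            items.append(QuestionItem(
                link_id=PREGNANCY_LINK_ID,
                text="Sind Sie derzeit schwanger?",
                item_type=SINGLE_CHOICE,
                options=(AnswerOption("yes", "ja"),
                         AnswerOption("no", "nein"),
                         AnswerOption("unknown", "unbekannt")),
                enable_conditions=(
                    EnableCondition(GENDER_LINK_ID, "not-equals", "male"),
                ),
            ))
            continue
        link_id = f"item-{counter:02d}"
        text = _sentence(rng, vocab, rng.randint(5, 9))
        if t == FREE_TEXT:
            item = QuestionItem(link_id=link_id, text=text, item_type=FREE_TEXT)
        else:
            n_opt = rng.randint(2, 4)
            options = tuple(
                AnswerOption(f"{link_id}-opt{k}", rng.choice(vocab))
                for k in range(1, n_opt + 1)
            )
            item = QuestionItem(link_id=link_id, text=text, item_type=t,
                                options=options)
        earlier_choice = [i for i in items if i.is_choice
                          and i.link_id != PREGNANCY_LINK_ID]
        if earlier_choice and rng.random() < spec.branch_fraction:
            src = rng.choice(earlier_choice)
            value = rng.choice([o.code for o in src.options])
            item = QuestionItem(
                link_id=item.link_id, text=item.text, item_type=item.item_type,
                options=item.options,
                enable_conditions=(EnableCondition(src.link_id, "equals", value),),
            )
        items.append(item)

    return QuestionnaireDef(
        canonical_url=f"urn:dmia:questionnaire:fixture-{spec.seed}",
        title=f"Synthetic interview fixture (seed {spec.seed})",
        items=tuple(items),
    )


def gen_task(questionnaire: QuestionnaireDef,
             patient: PatientIdentity = DEFAULT_PATIENT) -> TaskDef:
    """A fresh requested task for the given questionnaire."""
    return TaskDef(patient=patient,
                   questionnaire_url=questionnaire.canonical_url,
                   status="requested")


# ---------------------------------------------------------------------------
# Scripted sessions
# ---------------------------------------------------------------------------

POLICIES = ("random-valid", "always-first-option", "adversarial-skip")


def gen_scripted_session(
    questionnaire: QuestionnaireDef, policy: str = "random-valid", seed: int = 0
) -> dict:
    """A scripted-session document driving the full flow non-interactively.

    ``random-valid`` and ``always-first-option`` scripts answer every item
    validly (whatever branch is taken) and always complete;
    ``adversarial-skip`` blanks at least one always-enabled item so the
    engine's mandatory-answer check must fire.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    rng = random.Random(seed)
    vocab = _make_vocab(rng, _SYLLABLES_A, 40)
    answers: dict[str, object] = {}
    for item in questionnaire.answerable_items:
        if item.item_type == SINGLE_CHOICE:
            codes = [o.code for o in item.options]
            answers[item.link_id] = codes[0] if policy == "always-first-option" \
                else rng.choice(codes)
        elif item.item_type == MULTIPLE_CHOICE:
            codes = [o.code for o in item.options]
            if policy == "always-first-option":
                answers[item.link_id] = [codes[0]]
            else:
                answers[item.link_id] = rng.sample(
                    codes, rng.randint(1, min(3, len(codes))))
        else:
            answers[item.link_id] = " ".join(
                rng.choice(vocab) for _ in range(rng.randint(1, 6)))
    if policy == "adversarial-skip":
        first = questionnaire.answerable_items[0]
        answers[first.link_id] = ""  # mandatory-answer violation
    return {
        "seed": seed,
        "policy": policy,
        "identity": {},  # defaults to the task's patient
        "answers": answers,
        "qa_queries": [],
    }


# ---------------------------------------------------------------------------
# Knowledge base and labeled queries
# ---------------------------------------------------------------------------


def gen_kb(spec: FixtureSpec = FixtureSpec()) -> KnowledgeBase:
    """A knowledge base of ``kb_size`` unique synthetic question-answer pairs."""
    if spec.kb_size < 1:
        raise ValueError("kb_size must be >= 1")
    rng = random.Random(spec.seed + 1)
    vocab = _make_vocab(rng, _SYLLABLES_A, 160)
    pairs = []
    seen_questions: set[str] = set()
    for k in range(1, spec.kb_size + 1):
        while True:
            question = _sentence(rng, vocab, rng.randint(6, 9), "?")
            if question not in seen_questions:
                seen_questions.add(question)
                break
        answer = _sentence(rng, vocab, rng.randint(8, 14), ".")
        pairs.append(QAPair(id=f"qa-{k:03d}", question=question, answer=answer))
    return KnowledgeBase(pairs=tuple(pairs))


def paraphrase(question: str, strength: float, rng: random.Random) -> str:
    """Token-level perturbation: drop and adjacent-swap at rate *strength*.

    The result never falls below four tokens, so paraphrases always pass the
    length gate.
    """
    tokens = tokenize(question)
    kept = []
    dropped = 0
    for tok in tokens:
        if len(tokens) - dropped > 4 and rng.random() < strength:
            dropped += 1
            continue
        kept.append(tok)
    if len(kept) < 4:  # source shorter than the gate: keep it verbatim
        kept = list(tokens)
    for i in range(len(kept) - 1):
        if rng.random() < strength:
            kept[i], kept[i + 1] = kept[i + 1], kept[i]
    return " ".join(kept)


def gen_labeled_queries(
    kb: KnowledgeBase, spec: FixtureSpec = FixtureSpec()
) -> list[LabeledQuery]:
    """Labeled evaluation queries: in-KB paraphrases plus out-of-KB distractors.

    In-KB queries are paraphrases of knowledge-base questions (labelled with
    the source pair); out-of-KB queries are drawn from the onset-disjoint
    vocabulary, so the default lexical backend scores them 0 against every
    pair.
    """
    rng = random.Random(spec.seed + 2)
    out: list[LabeledQuery] = []
    for k in range(spec.n_in_kb):
        pair = kb.pairs[k % len(kb.pairs)]
        out.append(LabeledQuery(
            query=paraphrase(pair.question, spec.paraphrase_strength, rng),
            in_kb=True,
            correct_pair_id=pair.id,
        ))
    vocab_b = _make_vocab(rng, _SYLLABLES_B, 80)
    for _ in range(spec.n_out_kb):
        out.append(LabeledQuery(
            query=_sentence(rng, vocab_b, rng.randint(5, 8), "?"),
            in_kb=False,
        ))
    return out


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write questionnaire, task, KB, scripted session and labeled queries to disk
    in the formats the other modules read; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    questionnaire = gen_questionnaire(spec)
    task = gen_task(questionnaire)
    kb = gen_kb(spec)
    script = gen_scripted_session(questionnaire, "random-valid", spec.seed)
    queries = gen_labeled_queries(kb, spec)

    paths = {
        "questionnaire": outdir / "questionnaire.json",
        "task": outdir / "task.json",
        "kb": outdir / "knowledge_base.json",
        "script": outdir / "scripted_session.json",
        "queries": outdir / "labeled_queries.csv",
        "manifest": outdir / "manifest.json",
    }
    paths["questionnaire"].write_text(
        json.dumps(questionnaire_to_json(questionnaire), indent=2, ensure_ascii=False))
    paths["task"].write_text(json.dumps(task_to_json(task), indent=2, ensure_ascii=False))
    paths["kb"].write_text(json.dumps(kb_to_json(kb), indent=2, ensure_ascii=False))
    paths["script"].write_text(json.dumps(script, indent=2, ensure_ascii=False))
    lines = ["query,in_kb,correct_pair_id"]
    for lq in queries:
        lines.append(f"\"{lq.query}\",{str(lq.in_kb).lower()},{lq.correct_pair_id or ''}")
    paths["queries"].write_text("\n".join(lines) + "\n")
    paths["manifest"].write_text(json.dumps(
        {"seed": spec.seed, "spec": spec.__dict__}, indent=2))
    return paths
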