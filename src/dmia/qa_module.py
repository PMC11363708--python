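"""Retrieval-based examination Q&A over a curated knowledge base.

Free-text patient questions are matched against a set of predefined
question-answer pairs.  A query must contain more than three words to be
eligible at all; eligible queries are scored against every knowledge-base
question (and any alternative phrasings) and the best match's answer is
returned when its similarity reaches the threshold (default 0.7, cosine).
Below the threshold a standard fallback answer is given and the query is
appended to an unanswered-question store, which clinicians can periodically
review to extend the knowledge base.

The similarity backend is pluggable (any symmetric callable into [0, 1] with
sim(x, x) = 1 for non-empty x).  The default is a deterministic lexical
cosine over normalized unigram+bigram token counts: reproducible, with no
model artifacts to download.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

from .evaluation import ConfusionMatrix, LabeledQuery, classify_outcome

__all__ = [
    "QAPair",
    "KnowledgeBase",
    "QueryResult",
    "UnansweredStore",
    "ConfigurationError",
    "tokenize",
    "is_eligible",
    "CosineBackend",
    "similarity",
    "match",
    "review_unanswered",
    "add_pair",
    "sweep_threshold",
    "load_kb",
    "kb_to_json",
]

DEFAULT_THRESHOLD = 0.7
DEFAULT_MIN_WORDS = 4  # "more than 3 words": at least 4 tokens
DEFAULT_FALLBACK = (
    "I am sorry, I cannot answer this question. Please ask the hospital staff."
)
REFUSAL_MESSAGE = (
    "Could you please rephrase your question in a full sentence (more than three words)?"
)


class ConfigurationError(ValueError):
    """The knowledge base or matcher is misconfigured (e.g. empty KB)."""


# ---------------------------------------------------------------------------
# Tokenization and the length gate
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens: punctuation stripped, split on whitespace."""
    return _WORD_RE.findall(text.lower())


def is_eligible(query: str, min_words: int = DEFAULT_MIN_WORDS) -> bool:
    """Length gate: the module only handles queries of at least *min_words* tokens
    (by default more than three words)."""
    return len(tokenize(query)) >= min_words


# ---------------------------------------------------------------------------
# Similarity backends
# ---------------------------------------------------------------------------


class CosineBackend:
    """Cosine similarity over token unigram+bigram count vectors.

    Deterministic and dependency-free; serves as the default stand-in for an
    embedding-based matcher.  Satisfies the backend contract: symmetric,
    values in [0, 1], sim(x, x) = 1 for non-empty x, 0 when either side has
    no tokens.
    """

    def __init__(self, use_bigrams: bool = True):
        self.use_bigrams = use_bigrams

    def _vector(self, text: str) -> Counter:
        tokens = tokenize(text)
        grams: Counter = Counter(tokens)
        if self.use_bigrams:
            grams.update(zip(tokens, tokens[1:]))
        return grams

    def __call__(self, a: str, b: str) -> float:
        va, vb = self._vector(a), self._vector(b)
        if not va or not vb:
            return 0.0
        dot = sum(va[g] * vb[g] for g in va.keys() & vb.keys())
        norm = math.sqrt(sum(c * c for c in va.values())) * math.sqrt(
            sum(c * c for c in vb.values())
        )
        return min(1.0, dot / norm) if norm else 0.0


_DEFAULT_BACKEND = CosineBackend()

Backend = Callable[[str, str], float]


def similarity(a: str, b: str, backend: Backend | None = None) -> float:
    """Similarity of two texts in [0, 1] under the given (or default) backend."""
    return (backend or _DEFAULT_BACKEND)(a, b)


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QAPair:
    """One curated question-answer pair, optionally with alternative phrasings."""

    id: str
    question: str
    answer: str
    alternates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.question.strip():
            raise ValueError(f"pair {self.id!r}: question must be non-empty")
        if not self.answer.strip():
            raise ValueError(f"pair {self.id!r}: answer must be non-empty")

    def phrasings(self) -> tuple[str, ...]:
        return (self.question, *self.alternates)


@dataclass(frozen=True)
class KnowledgeBase:
    pairs: tuple[QAPair, ...]
    fallback_answer: str = DEFAULT_FALLBACK
    threshold: float = DEFAULT_THRESHOLD
    min_words: int = DEFAULT_MIN_WORDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.min_words < 1:
            raise ConfigurationError(f"min_words must be >= 1, got {self.min_words}")
        ids = [p.id for p in self.pairs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate pair ids: {dup}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class QueryResult:
    """Outcome of matching one query: best pair, its similarity, answered flag."""

    query: str
    eligible: bool
    best_pair_id: str | None
    best_similarity: float
    answered: bool
    answer_text: str


@dataclass
class UnansweredStore:
    """Append-only store of eligible-but-unanswered queries, for clinician review."""

    entries: list[tuple[str, float]] = field(default_factory=list)
    _clock: int = 0

    def append(self, query: str) -> None:
        self._clock += 1
        self.entries.append((query, float(self._clock)))

    def __len__(self) -> int:
        return len(self.entries)

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps({"query": q, "timestamp": t}, ensure_ascii=False)
            for q, t in self.entries
        )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match(
    query: str,
    kb: KnowledgeBase,
    backend: Backend | None = None,
    store: UnansweredStore | None = None,
) -> QueryResult:
    """Match one query against the knowledge base.

    Short queries (fewer than ``kb.min_words`` tokens) are refused outright
    and are *not* stored as unanswered — they are malformed input, not
    unanswerable content.  Otherwise the best-scoring pair (over canonical
    questions and alternates, ties broken by lowest pair id) answers the
    query when its similarity reaches ``kb.threshold``; below it the fallback
    answer is returned and the query appended to *store*.
    """
    if not kb.pairs:
        raise ConfigurationError("knowledge base is empty")
    backend = backend or _DEFAULT_BACKEND
    if not is_eligible(query, kb.min_words):
        return QueryResult(
            query=query,
            eligible=False,
            best_pair_id=None,
            best_similarity=0.0,
            answered=False,
            answer_text=REFUSAL_MESSAGE,
        )
    best_id: str | None = None
    best_sim = -1.0
    for pair in sorted(kb.pairs, key=lambda p: p.id):
        sim = max(backend(query, phrasing) for phrasing in pair.phrasings())
        if sim > best_sim:  # strict: earlier (lower) id wins ties
            best_sim = sim
            best_id = pair.id
    best_sim = max(0.0, best_sim)
    if best_sim >= kb.threshold:
        answer = next(p.answer for p in kb.pairs if p.id == best_id)
        return QueryResult(query, True, best_id, best_sim, True, answer)
    if store is not None:
        store.append(query)
    return QueryResult(query, True, best_id, best_sim, False, kb.fallback_answer)


# ---------------------------------------------------------------------------
# Review loop
# ---------------------------------------------------------------------------


def review_unanswered(store: UnansweredStore) -> list[str]:
    """Unanswered queries in insertion order, for clinician review."""
    return [q for q, _ in store.entries]


def add_pair(
    kb: KnowledgeBase,
    question: str,
    answer: str,
    id: str | None = None,
    alternates: Sequence[str] = (),
) -> KnowledgeBase:
    """Extend the knowledge base with a reviewed question-answer pair.

    Returns a new knowledge base; the original is untouched.  A previously
    unanswered query added verbatim is afterwards answered at any threshold
    up to 1 (it matches itself with similarity 1).
    """
    if id is None:
        existing = {p.id for p in kb.pairs}
        n = len(kb.pairs) + 1
        while f"qa-{n:03d}" in existing:
            n += 1
        id = f"qa-{n:03d}"
    elif any(p.id == id for p in kb.pairs):
        raise ConfigurationError(f"duplicate pair id {id!r}")
    new_pair = QAPair(id=id, question=question, answer=answer, alternates=tuple(alternates))
    return replace(kb, pairs=kb.pairs + (new_pair,))


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def sweep_threshold(
    labeled_queries: Sequence[LabeledQuery],
    kb: KnowledgeBase,
    backend: Backend | None = None,
    thresholds: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> list[tuple[float, ConfusionMatrix]]:
    """Confusion matrix of the matcher at each threshold (ascending).

    Raising the threshold trades false positives for false negatives: the
    answered count, TP and FP are all non-increasing in the threshold.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    out = []
    for t in thresholds:
        # thresholds above 1 are legal sweep points: no similarity reaches them
        kb_t = replace(kb, threshold=min(t, 1.0))
        tp = fp = fn = tn = 0
        for lq in labeled_queries:
            result = match(lq.query, kb_t, backend=backend)
            if t > 1.0:
                result = replace(result, answered=False)
            correct = (
                result.answered
                and lq.in_kb
                and result.best_pair_id == lq.correct_pair_id
            )
            outcome = classify_outcome(lq.in_kb, result.answered, correct)
            if outcome == "TP":
                tp += 1
            elif outcome == "FP":
                fp += 1
            elif outcome == "FN":
                fn += 1
            else:
                tn += 1
        out.append((t, ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)))
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def load_kb(
    text: str,
    fmt: str = "json",
    *,
    fallback_answer: str = DEFAULT_FALLBACK,
    threshold: float = DEFAULT_THRESHOLD,
    min_words: int = DEFAULT_MIN_WORDS,
) -> KnowledgeBase:
    """Read a knowledge base from JSON (list of pair objects, optionally under
    a top-level config) or CSV with an ``id,question,answer[,alternates]`` header."""
    if fmt == "json":
        doc = json.loads(text)
        config = {}
        if isinstance(doc, dict):
            config = doc.get("config", {})
            doc = doc["pairs"]
        pairs = [
            QAPair(
                id=str(p["id"]),
                question=p["question"],
                answer=p["answer"],
                alternates=tuple(p.get("alternates", ())),
            )
            for p in doc
        ]
        return KnowledgeBase(
            pairs=tuple(pairs),
            fallback_answer=config.get("fallback_answer", fallback_answer),
            threshold=config.get("threshold", threshold),
            min_words=config.get("min_words", min_words),
        )
    if fmt == "csv":
        reader = csv.DictReader(io.StringIO(text))
        pairs = [
            QAPair(
                id=row["id"],
                question=row["question"],
                answer=row["answer"],
                alternates=tuple(
                    a for a in (row.get("alternates") or "").split("|") if a
                ),
            )
            for row in reader
        ]
        return KnowledgeBase(
            pairs=tuple(pairs),
            fallback_answer=fallback_answer,
            threshold=threshold,
            min_words=min_words,
        )
    raise ValueError(f"unknown knowledge-base format {fmt!r}")


def kb_to_json(kb: KnowledgeBase) -> dict:
    return {
        "config": {
            "fallback_answer": kb.fallback_answer,
            "threshold": kb.threshold,
            "min_words": kb.min_words,
        },
        "pairs": [
            {
                "id": p.id,
                "question": p.question,
                "answer": p.answer,
                **({"alternates": list(p.alternates)} if p.alternates else {}),
            }
            for p in kb.pairs
        ],
    }
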