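"""Measurement stack: retrieval metrics, readability indices, usability scoring.

Four building blocks, mirroring how retrieval-based patient-facing chatbots
are commonly assessed:

* **Outcome classification** of labeled queries into TP/FP/FN/TN.  A query is
  a true positive when an answer for it exists in the knowledge base and it
  was answered *correctly*; answered-but-wrong or answered-without-a-KB-entry
  are false positives; in-KB-but-unanswered is a false negative; out-of-KB and
  unanswered is a true negative.  Correctness is a human judgment supplied as
  a label, never computed here.
* **Retrieval metrics** (precision, recall, F1, accuracy) from a confusion
  matrix, reported at full precision with half-up 2-decimal rounding for
  display.
* **Readability indices** — LIX, Flesch Reading Ease (German/Amstad and
  English variants), Gunning Fog and SMOG — from surface text statistics with
  language-tagged vowel-group syllable counting.  The syllable counter is an
  explicit approximation; third-party calculators may differ.
* **Usability instruments** — per-item summaries of 5-point Likert responses
  (BUS-11 style, "agreement" = top-two box) and of a 1-3-point heuristic
  rubric whose maximum is three points per heuristic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "LabeledQuery",
    "ConfusionMatrix",
    "RetrievalMetrics",
    "TextStats",
    "ReadabilityScores",
    "classify_outcome",
    "confusion_from_outcomes",
    "retrieval_metrics",
    "round_half_up",
    "count_syllables",
    "text_stats",
    "lix",
    "flesch_reading_ease",
    "gunning_fog",
    "smog",
    "readability_scores",
    "bus11_summary",
    "BUS11_ITEMS",
    "heuristic_summary",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at *ndigits* decimals (printed-value convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Retrieval outcomes and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledQuery:
    """A query with ground truth: is an answer in the KB, and which pair is correct."""

    query: str
    in_kb: bool
    correct_pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.in_kb != (self.correct_pair_id is not None):
            raise ValueError("correct_pair_id must be present iff in_kb")


def classify_outcome(in_kb: bool, answered: bool, correct: bool = False) -> str:
    """Classify one query outcome as ``"TP"``, ``"FP"``, ``"FN"`` or ``"TN"``.

    TP: in the KB and correctly answered.  FP: answered, but either not in
    the KB or answered with the wrong pair.  FN: in the KB but unanswered.
    TN: not in the KB and unanswered.  Exactly one class applies to every
    (in_kb, answered, correct) combination.
    """
    if answered:
        return "TP" if (in_kb and correct) else "FP"
    return "FN" if in_kb else "TN"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion_from_outcomes(outcomes: list[str]) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=outcomes.count("TP"),
        fp=outcomes.count("FP"),
        fn=outcomes.count("FN"),
        tn=outcomes.count("TN"),
    )


@dataclass(frozen=True)
class RetrievalMetrics:
    precision: float
    recall: float
    f1: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> "RetrievalMetrics":
        return RetrievalMetrics(
            *(round_half_up(v, ndigits)
              for v in (self.precision, self.recall, self.f1, self.accuracy))
        )


def retrieval_metrics(cm: ConfusionMatrix) -> RetrievalMetrics:
    """Precision, recall, F1 and accuracy; zero-denominator conventions give 0."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    precision = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    accuracy = (cm.tp + cm.tn) / cm.total
    return RetrievalMetrics(precision, recall, f1, accuracy)


# ---------------------------------------------------------------------------
# Text statistics and syllables
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)  # letter runs only
_SENTENCE_END_RE = re.compile(r"[.!?…]+(?=\s|$)")

_VOWELS = {
    "de": set("aeiouäöüy"),
    "en": set("aeiouy"),
}
# Vowel sequences pronounced as one syllable nucleus.
_DIPHTHONGS = {
    "de": ("äu", "au", "ei", "eu", "ie"),
    "en": ("ai", "au", "ay", "ea", "ee", "ei", "ey", "ie",
           "oa", "oo", "ou", "oy", "ue", "ui"),
}


def count_syllables(word: str, language: str = "de") -> int:
    """Approximate syllable count by vowel-group counting with a diphthong table.

    Each maximal vowel run contributes one unit per greedily-consumed
    diphthong or single vowel; English words ending in silent 'e' lose one.
    Every non-empty word has at least one syllable.
    """
    if language not in _VOWELS:
        raise ValueError(f"unsupported language {language!r}")
    vowels = _VOWELS[language]
    diphthongs = _DIPHTHONGS[language]
    w = word.lower()
    count = 0
    i = 0
    while i < len(w):
        if w[i] not in vowels:
            i += 1
            continue
        # inside a vowel run: greedily consume diphthongs, else single vowels
        for d in diphthongs:
            if w.startswith(d, i):
                i += len(d)
                break
        else:
            i += 1
        count += 1
    if language == "en" and count > 1 and w.endswith("e") and not w.endswith(("le", "ee")):
        count -= 1
    return max(count, 1) if w else 0


@dataclass(frozen=True)
class TextStats:
    sentences: int
    words: int
    long_words: int  # words of 7+ letters
    polysyllables: int  # words of 3+ syllables
    syllables: int


def text_stats(text: str, language: str = "de") -> TextStats:
    """Surface statistics of a text: sentence, word, long-word, syllable counts.

    Sentences end at ``.``, ``!``, ``?`` or ``…`` followed by whitespace or
    the end of the text; non-empty text without a terminator counts as one
    sentence.  Words are maximal letter runs.
    """
    if language not in _VOWELS:
        raise ValueError(f"unsupported language {language!r}")
    if not text.strip():
        return TextStats(0, 0, 0, 0, 0)
    sentences = len(_SENTENCE_END_RE.findall(text))
    if sentences == 0 or _SENTENCE_END_RE.split(text)[-1].strip():
        sentences += 1  # trailing clause without terminator
    words = _WORD_RE.findall(text)
    syl = [count_syllables(w, language) for w in words]
    return TextStats(
        sentences=sentences,
        words=len(words),
        long_words=sum(1 for w in words if len(w) >= 7),
        polysyllables=sum(1 for s in syl if s >= 3),
        syllables=sum(syl),
    )


# ---------------------------------------------------------------------------
# Readability indices
# ---------------------------------------------------------------------------


def _require_words(stats: TextStats) -> None:
    if stats.words == 0 or stats.sentences == 0:
        raise ValueError("readability indices need non-empty text")


def lix(stats: TextStats) -> float:
    """LIX = words/sentences + 100 * long_words/words (long = 7+ letters)."""
    _require_words(stats)
    return stats.words / stats.sentences + 100.0 * stats.long_words / stats.words


FLESCH_VARIANTS = ("german_amstad", "english")


def flesch_reading_ease(stats: TextStats, variant: str = "german_amstad") -> float:
    """Flesch Reading Ease; the Amstad adaptation recalibrates it for German.

    german_amstad: 180 - ASL - 58.5 * ASW;
    english: 206.835 - 1.015 * ASL - 84.6 * ASW,
    with ASL = words/sentence and ASW = syllables/word.
    """
    _require_words(stats)
    asl = stats.words / stats.sentences
    asw = stats.syllables / stats.words
    if variant == "german_amstad":
        return 180.0 - asl - 58.5 * asw
    if variant == "english":
        return 206.835 - 1.015 * asl - 84.6 * asw
    raise ValueError(f"unknown Flesch variant {variant!r}")


def gunning_fog(stats: TextStats) -> float:
    """Gunning Fog = 0.4 * (ASL + 100 * polysyllables/words)."""
    _require_words(stats)
    return 0.4 * (stats.words / stats.sentences + 100.0 * stats.polysyllables / stats.words)


def smog(stats: TextStats) -> float:
    """SMOG = 1.0430 * sqrt(polysyllables * 30/sentences) + 3.1291."""
    if stats.sentences == 0:
        raise ValueError("SMOG needs at least one sentence")
    return 1.0430 * math.sqrt(stats.polysyllables * 30.0 / stats.sentences) + 3.1291


@dataclass(frozen=True)
class ReadabilityScores:
    lix: float
    flesch_reading_ease: float
    gunning_fog: float
    smog: float
    flesch_variant: str = "german_amstad"


def readability_scores(
    text: str, language: str = "de", flesch_variant: str = "german_amstad"
) -> ReadabilityScores:
    """All four indices of one text in one call."""
    stats = text_stats(text, language)
    return ReadabilityScores(
        lix=lix(stats),
        flesch_reading_ease=flesch_reading_ease(stats, flesch_variant),
        gunning_fog=gunning_fog(stats),
        smog=smog(stats),
        flesch_variant=flesch_variant,
    )


# ---------------------------------------------------------------------------
# Usability instruments
# ---------------------------------------------------------------------------

#: The 11 item ids of the Bot Usability Scale questionnaire.
BUS11_ITEMS = tuple(f"BUS11_SQ{n:03d}" for n in range(1, 12))


def bus11_summary(
    responses: pd.DataFrame, agree_levels: tuple[int, ...] = (4, 5)
) -> pd.DataFrame:
    """Per-item n, mean and percent agreement for 5-point Likert responses.

    *responses* is respondent x item; missing cells (NaN) are excluded from
    the denominator.  Agreement is the top-two-box share (4 or 5) among
    non-missing responses, as a percentage.
    """
    values = responses.to_numpy(dtype=float)
    finite = values[~pd.isna(values)]
    if len(finite) and ((finite < 1) | (finite > 5) | (finite % 1 != 0)).any():
        raise ValueError("Likert responses must be integers in 1..5")
    n = responses.notna().sum(axis=0)
    if (n == 0).any():
        raise ValueError("every item needs at least one response")
    mean = responses.mean(axis=0, skipna=True)
    agree = responses.isin(agree_levels).sum(axis=0) / n * 100.0
    return pd.DataFrame({"n": n, "mean": mean, "percent_agreement": agree})


def heuristic_summary(ratings: pd.DataFrame) -> dict:
    """Per-heuristic n and mean for a 1-3-point rubric, plus the rubric total.

    Returns ``{"per_heuristic": DataFrame, "sum_of_means": float,
    "max_possible": int}`` where max_possible is 3 points per heuristic.
    Missing cells are excluded from each heuristic's denominator.
    """
    values = ratings.to_numpy(dtype=float)
    finite = values[~pd.isna(values)]
    if len(finite) and (~pd.Series(finite).isin([1, 2, 3])).any():
        raise ValueError("heuristic scores must be in {1, 2, 3}")
    n = ratings.notna().sum(axis=0)
    if (n == 0).any():
        raise ValueError("every heuristic needs at least one rating")
    mean = ratings.mean(axis=0, skipna=True)
    per = pd.DataFrame({"n": n, "mean": mean})
    return {
        "per_heuristic": per,
        "sum_of_means": float(mean.sum()),
        "max_possible": 3 * ratings.shape[1],
    }
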