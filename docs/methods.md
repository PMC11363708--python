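# Methods

## The dialogue model

A session is a state machine over the phases `onboarding → interview → qa →
confirmation → submitted`, with `suspended` reachable only from onboarding.
The model assumes one patient, one task, one questionnaire per session, and a
strictly turn-based conversation recorded as a timestamped transcript.

**Onboarding.**  The patient is welcomed, told how their data are handled,
and asked for full name and birth date.  The claimed identity is compared
with the task's Patient resource: names are NFKC-normalized, case-folded,
punctuation-stripped and compared as *token multisets*, so "Muster Erika"
matches "Erika Muster" — users are commonly unsure of the expected name
order, and order carries no identifying information here.  Birth dates must
match exactly.  `max_auth_attempts` defaults to 1: a single wrong attempt
suspends the session and the task, and the agent directs the patient to
hospital staff.  A suspended session accepts no further operations.

**Interview.**  Items are asked in authoring order; an item is eligible when
its `enableWhen` conditions hold against the answers recorded so far.  The
supported operators are `equals`, `not-equals` and `answered` — interview
branching is driven purely by coded choice answers, so no numeric comparators
are needed.  Semantics: `equals` passes if *any* recorded answer of the
source matches (FHIR any-answer semantics); `not-equals` passes if the source
was answered and no recorded answer matches; any condition on an unanswered
source evaluates false.  Because questionnaires are validated to contain no
forward references, a condition's source is always asked before its
dependent, which guarantees progress: a valid answer policy always reaches
confirmation.  All posed questions are mandatory; single-choice items take
exactly one option, multiple-choice at least one, and free text is stored
verbatim and never interpreted.  `display` items are rendered into the
transcript but are not answerable.

**Q&A, confirmation, submission.**  After the last interview item the session
enters the Q&A phase automatically; the user ends it with an explicit done
signal, and asking zero questions is allowed (whether the phase can be
skipped outright is not constrained by the flow, so the permissive choice was
made).  The confirmation summary is read-only — editing answers from the
summary is deliberately rejected.  Submission populates the
`QuestionnaireResponse` (only enabled, answered items), completes the task,
and emits the transcript as JSON lines, one turn per line, including the Q&A
turns.  Timestamps come from an injectable clock so scripted runs are
bit-for-bit reproducible.

## FHIR mapping and validation

Only FHIR R4 JSON is supported (the SDC tooling this targets is R4-based).
Profile conformance is enforced structurally against the invariants of the
domain types — unique `linkId`s, ≥2 options on choice items, no options on
free-text/display items, no forward `enableWhen` references, condition
values drawn from the source item's options — rather than by a generic
StructureDefinition validator; there is no terminology binding.  Validators
return *all* violations.  Single- vs multiple-choice is encoded as FHIR
`choice` with `repeats`.  Choice answers are carried as `valueCoding` codes
and free text as `valueString`; if deposited profiles of a comparable system
encode choices differently (e.g. plain strings), the reader accepts
`valueString` options as a fallback.  A missing `enableBehavior` with more
than one condition defaults to `all` but is surfaced as a warning violation,
since FHIR requires it to be explicit.

## Q&A matching

Tokenization lowercases, strips punctuation and splits on whitespace.  The
length gate requires strictly more than 3 tokens (`min_words = 4`); shorter
queries are refused with a distinct message and are *not* appended to the
unanswered store — they are malformed input rather than unanswerable
content (an interpretation; the alternative of storing them would only add
noise to clinician review).  Eligible queries are scored against every
pair's canonical question and alternates; the pair's score is the maximum
over its phrasings, ties break to the lowest pair id.  At similarity ≥
threshold (default 0.7) the pair's answer is returned verbatim; otherwise
the fallback answer is returned and the query stored append-only for
periodic clinician review (`add_pair` closes the loop and never decreases
any query's best similarity).

The default backend is a cosine over unigram+bigram token count vectors.  A
production system would use sentence embeddings; the backend is therefore a
pluggable callable constrained to be symmetric, in [0, 1], and 1 on
identical non-empty inputs, and every result above holds for any conforming
backend.  The lexical default is chosen for determinism and zero model
downloads.

## Evaluation conventions

* Outcome labels: TP = in-KB and correctly answered; FP = answered but
  out-of-KB **or** answered with the wrong pair (an answered query cannot be
  a true positive unless correct, and the four labels are exhaustive);
  FN = in-KB, unanswered; TN = out-of-KB, unanswered.  Correctness is a
  human judgment supplied as a label.
* Metrics use the zero-denominator convention (0), and are reported at full
  precision with half-up rounding to 2 decimals for display.
* Readability: LIX = W/S + 100·LW/W (LW = words of ≥7 letters);
  Flesch Reading Ease = 180 − ASL − 58.5·ASW (Amstad, German; default
  because the engine's content language is German) or 206.835 − 1.015·ASL −
  84.6·ASW (English); Gunning Fog = 0.4·(ASL + 100·PSW/W) (PSW = words of ≥3
  syllables); SMOG = 1.0430·√(PSW·30/S) + 3.1291.  Sentences end at
  `.!?…` before whitespace/end; a trailing unterminated clause counts as one
  sentence.  Syllables are counted by a language-tagged vowel-group scan
  with an explicit diphthong table (German: au, ei, eu, äu, ie; English
  adds the common digraphs and a silent-final-e rule).  This is an
  approximation — third-party calculators hyphenate differently — so only
  the closed-form arithmetic is asserted, never external calculators'
  published values for particular corpora.
* Likert "agreement" is the top-two-box share (4 or 5 on the 5-point scale),
  configurable; missing cells shrink the item's denominator.  The heuristic
  rubric scores 1–3 per heuristic, so `max_possible = 3·H` (33 for the
  standard 11-heuristic set).

## Synthetic fixtures

The generator emulates the *structure* of a deployed breast-imaging
interview assistant, not its content: questionnaires default to 18
single-choice + 7 multiple-choice + 6 free-text items (31 answerable), always
including a gender item and a pregnancy item conditioned on
`gender not-equals male`; a further `branch_fraction = 0.2` of items get an
equals-condition on a random earlier choice item (a light-branching regime;
the reference flow branches on a minority of items).  Knowledge bases
default to 33 pairs.  Labeled query sets default to 54 in-KB paraphrases and
60 out-of-KB distractors — the 114-query split of the reference evaluation
(54 = 47 TP + 7 FN in-KB, 60 = 46 FP + 14 TN out-of-KB).  Paraphrases drop
and swap tokens at rate `paraphrase_strength = 0.2`, never below the
4-token gate; distractors are drawn from a syllable inventory whose word
onsets are disjoint from the KB's, so the lexical backend scores them
exactly 0.

Because of that construction the synthetic benchmark lacks two features of
real patient queries: out-of-KB questions that *share* vocabulary with the
KB (the source of real false positives at high thresholds) and in-KB
questions rephrased beyond token edits.  Passing tests therefore demonstrate
the mechanics (gating, thresholding, monotone trade-off, bookkeeping), not
field accuracy.  Generated text is German-like token strings; readability
values of fixtures are meaningless and are never asserted.

Generation is pure given (spec, seed): one seeded PRNG stream per generator
call, with seeds recorded in the written files.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full flow at the default
31-item/33-pair scale and sweep 21 thresholds over 114 queries; round-trip
identity is checked over ≥1000 generated questionnaire/response instances
and branch soundness over 1000 scripted sessions — sizes chosen to exercise
every code path while keeping the whole suite in the tens of seconds.
Similarity comparisons use exact float cosine with no tolerance; the
threshold test is `≥`.  Readability formulas are asserted to 1e-9 against
hand-computed closed forms.  Degenerate inputs are defined explicitly: empty
text has zero stats and no readability scores (error), empty queries are
ineligible, an empty knowledge base is a configuration error, and an empty
questionnaire is valid and goes straight to the Q&A phase.

## Known limitations

* No web/tablet UI, no live hospital-system transport; transport is
  file-based (scripted sessions in, response + transcript out).
* Free text is never interpreted, matching the reference behaviour.
* The lexical backend under-models semantic similarity; threshold values
  tuned on it do not transfer to embedding backends.
* Structural validation is not a substitute for full FHIR profile
  validation against StructureDefinitions.
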