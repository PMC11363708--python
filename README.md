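# dmia — a digital medical interview assistant engine

`dmia` is a reusable engine for pre-consultation medical interview chatbots
(digital medical interview assistants, DMIAs): systems that collect a
patient's medical history on a tablet before an examination — for example a
mammography — and return the answers as structured, interoperable data.  It
is aimed at clinical-informatics researchers and developers who want to
build, script or evaluate such a system without a web front end or a
hospital information system attached.

The engine has three parts:

1. **FHIR-driven branching interview.**  The interview content is an HL7 FHIR
   R4 `Questionnaire` (Structured Data Capture style).  A dialogue state
   machine runs onboarding (welcome, data-handling notice, authentication by
   full name and birth date against the task's `Patient`), then the interview
   itself.  `enableWhen` conditions on items drive branching — a pregnancy
   question is only asked when the patient states not to be male.  All posed
   questions are mandatory, free text is stored verbatim, and a completed
   session populates a `QuestionnaireResponse` plus a JSON-lines transcript
   log.  Authentication fails safe: wrong credentials suspend the session and
   direct the patient to hospital staff.
2. **Retrieval Q&A.**  Free-text questions about the examination are matched
   against a curated knowledge base of question-answer pairs.  A query must
   contain more than three words; the best-scoring pair answers it when its
   similarity reaches the threshold *t* (default 0.7, cosine), otherwise a
   fallback answer is returned and the query is stored for clinician review.
   The similarity backend is pluggable; the default is a deterministic
   lexical cosine over unigram+bigram token counts.
3. **Evaluation toolkit.**  Labeled queries are classified into TP / FP / FN /
   TN (a true positive is an in-KB query answered *correctly*; an answered
   out-of-KB or wrongly answered query is a false positive), with precision =
   TP/(TP+FP), recall = TP/(TP+FN), F1 and accuracy.  Readability of chatbot
   content is scored with LIX, Flesch Reading Ease (German/Amstad and English
   variants), Gunning Fog and SMOG.  Usability instruments are summarised
   per item: 5-point Likert scales (BUS-11 style, agreement = top-two box)
   and a 1–3-point heuristic rubric (maximum 3·H points).

A deterministic fixture generator produces branching questionnaires,
scripted sessions, knowledge bases and labeled query sets, so the whole
pipeline runs from a seed with no external artifacts.

## Worked example

Generate fixtures, run a scripted interview, and evaluate the Q&A module:

```sh
$ dmia fixtures --seed 0 --out fxdemo
$ dmia interview --task fxdemo/task.json \
    --questionnaire fxdemo/questionnaire.json \
    --script fxdemo/scripted_session.json \
    --kb fxdemo/knowledge_base.json --out run1
submitted: 28 answer groups, 62 transcript turns -> run1
```

The scripted session answered 28 of the questionnaire's 31 items — the other
3 were disabled by branching on the answers given — and `run1/` now holds the
populated `QuestionnaireResponse` and the transcript log.

Evaluating a published confusion matrix of 114 labeled patient queries
(47 TP, 46 FP, 7 FN, 14 TN):

```sh
$ dmia eval --confusion 47 46 7 14
TP=47 FP=46 FN=7 TN=14 (n=114)
precision=0.51 recall=0.87 f1=0.64 accuracy=0.54
```

Roughly half of all given answers were right (precision 0.51) while most
answerable questions did get answered (recall 0.87).  Sweeping the
similarity threshold on the synthetic benchmark shows the trade-off that
governs this operating point — raising *t* removes false positives first,
then starts costing true positives:

```sh
$ dmia sweep --kb fxdemo/knowledge_base.json \
    --labeled fxdemo/labeled_queries.csv --thresholds 0,0.5,0.7,0.9
thr   TP  FP  FN  TN  prec  rec   f1    acc
0.0   54  60  0   0   0.47  1.0   0.64  0.47
0.5   50  0   4   60  1.0   0.93  0.96  0.96
0.7   24  0   30  60  1.0   0.44  0.62  0.74
0.9   8   0   46  60  1.0   0.15  0.26  0.6
```

(The synthetic benchmark separates in- and out-of-KB vocabulary perfectly,
so its precision at high thresholds is optimistic; see `docs/methods.md`.)

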