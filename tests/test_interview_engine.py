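"""Dialogue state machine: authentication, branching, mandatory answers, submission."""

import datetime as dt
import json

import pytest

from dmia import fhir_model as fm
from dmia import fixtures as fx
from dmia import interview_engine as eng
from dmia.fhir_model import PatientIdentity


def _session(questionnaire, **kw):
    return eng.start_session(fx.gen_task(questionnaire), questionnaire, **kw)


class TestOnboarding:
    def test_start_session_welcomes_and_marks_in_progress(self, questionnaire, task):
        session = eng.start_session(task, questionnaire)
        assert session.phase == "onboarding"
        assert task.status == "in-progress"
        assert len(session.transcript) >= 1
        assert session.transcript[0].speaker == "agent"
        # the welcome covers how data are handled
        assert "handled" in session.transcript[0].text

    def test_mismatched_questionnaire_url_is_rejected(self, questionnaire, task):
        task.questionnaire_url = "urn:other"
        with pytest.raises(eng.StateError):
            eng.start_session(task, questionnaire)

    def test_exact_identity_authenticates(self, questionnaire, patient):
        session = _session(questionnaire)
        assert eng.authenticate(session, patient) == "authenticated"
        assert session.phase == "interview"

    def test_wrong_birth_date_suspends_immediately(self, questionnaire):
        session = _session(questionnaire)  # max_auth_attempts defaults to 1
        wrong = PatientIdentity("Erika Muster", dt.date(1970, 1, 2))
        assert eng.authenticate(session, wrong) == "suspended"
        assert session.phase == "suspended"
        assert session.task.status == "suspended"
        # patient is directed to hospital staff
        assert "staff" in session.transcript[-1].text

    def test_reordered_case_folded_name_authenticates(self, questionnaire):
        session = _session(questionnaire)
        claimed = PatientIdentity("  muster   ERIKA ", dt.date(1970, 1, 1))
        assert eng.authenticate(session, claimed) == "authenticated"

    def test_retry_then_success_with_two_attempts(self, questionnaire, patient):
        session = _session(questionnaire, max_auth_attempts=2)
        wrong = PatientIdentity("Max Muster", patient.birth_date)
        assert eng.authenticate(session, wrong) == "retry"
        assert session.phase == "onboarding"
        assert eng.authenticate(session, patient) == "authenticated"

    def test_suspended_session_refuses_further_operations(self, questionnaire):
        session = _session(questionnaire)
        eng.authenticate(session, PatientIdentity("X Y", dt.date(2000, 1, 1)))
        assert session.phase == "suspended"
        with pytest.raises(eng.StateError):
            eng.next_item(session)
        with pytest.raises(eng.StateError):
            eng.authenticate(session, PatientIdentity("X Y", dt.date(2000, 1, 1)))

    def test_authenticate_outside_onboarding_is_a_state_error(
            self, questionnaire, patient):
        session = _session(questionnaire)
        eng.authenticate(session, patient)
        with pytest.raises(eng.StateError):
            eng.authenticate(session, patient)


class TestBranching:
    def test_male_answer_skips_pregnancy_item(self, questionnaire, patient):
        session = _session(questionnaire)
        eng.authenticate(session, patient)
        asked = []
        while (item := eng.next_item(session)) is not None:
            asked.append(item.link_id)
            if item.link_id == fx.GENDER_LINK_ID:
                eng.record_answer(session, item.link_id, "male")
            elif item.item_type == fm.FREE_TEXT:
                eng.record_answer(session, item.link_id, "freitext antwort")
            else:
                eng.record_answer(session, item.link_id, item.options[0].code)
        assert fx.PREGNANCY_LINK_ID not in asked
        assert fx.PREGNANCY_LINK_ID not in session.answers

    def test_non_male_answer_reaches_pregnancy_item(self, questionnaire, patient):
        session = _session(questionnaire)
        eng.authenticate(session, patient)
        asked = []
        while (item := eng.next_item(session)) is not None:
            asked.append(item.link_id)
            if item.link_id == fx.GENDER_LINK_ID:
                eng.record_answer(session, item.link_id, "female")
            elif item.item_type == fm.FREE_TEXT:
                eng.record_answer(session, item.link_id, "text")
            else:
                eng.record_answer(session, item.link_id, item.options[0].code)
        assert fx.PREGNANCY_LINK_ID in asked

    def test_unconditioned_questionnaire_returns_all_items_in_order(self, patient):
        # n_single=1 suppresses the gender/pregnancy pair, which always branches
        q = fx.gen_questionnaire(fx.FixtureSpec(
            seed=3, n_single=1, n_multi=2, n_free=1, branch_fraction=0.0))
        assert all(not i.enable_conditions for i in q.items)
        session = _session(q)
        eng.authenticate(session, patient)
        order = []
        while (item := eng.next_item(session)) is not None:
            order.append(item.link_id)
            eng.record_answer(
                session, item.link_id,
                item.options[0].code if item.is_choice else "x y")
        assert order == [i.link_id for i in q.answerable_items]
        assert session.phase == "qa"

    def test_is_enabled_semantics(self):
        src = fm.QuestionItem("src", "?", fm.MULTIPLE_CHOICE,
                              options=(fm.AnswerOption("a"), fm.AnswerOption("b"),
                                       fm.AnswerOption("c")))
        eq = fm.QuestionItem("eq", "?", fm.FREE_TEXT, enable_conditions=(
            fm.EnableCondition("src", "equals", "b"),))
        ne = fm.QuestionItem("ne", "?", fm.FREE_TEXT, enable_conditions=(
            fm.EnableCondition("src", "not-equals", "b"),))
        ans = fm.QuestionItem("ans", "?", fm.FREE_TEXT, enable_conditions=(
            fm.EnableCondition("src", "answered"),))
        nothing = {}
        multi = {"src": (fm.AnswerValue("coded", "a"), fm.AnswerValue("coded", "b"))}
        only_a = {"src": (fm.AnswerValue("coded", "a"),)}
        # unanswered source -> false, even for not-equals
        assert not eng.is_enabled(eq, nothing)
        assert not eng.is_enabled(ne, nothing)
        assert not eng.is_enabled(ans, nothing)
        # equals passes if any recorded answer matches (any-answer semantics)
        assert eng.is_enabled(eq, multi)
        assert not eng.is_enabled(eq, only_a)
        # not-equals requires no recorded answer to match
        assert not eng.is_enabled(ne, multi)
        assert eng.is_enabled(ne, only_a)
        assert eng.is_enabled(ans, only_a)

    def test_enable_behavior_any_vs_all(self):
        conds = (fm.EnableCondition("src", "equals", "a"),
                 fm.EnableCondition("src", "equals", "b"))
        item_all = fm.QuestionItem("x", "?", fm.FREE_TEXT,
                                   enable_conditions=conds, enable_behavior="all")
        item_any = fm.QuestionItem("y", "?", fm.FREE_TEXT,
                                   enable_conditions=conds, enable_behavior="any")
        only_a = {"src": (fm.AnswerValue("coded", "a"),)}
        assert not eng.is_enabled(item_all, only_a)
        assert eng.is_enabled(item_any, only_a)


class TestRecordAnswer:
    @pytest.fixture
    def live(self, questionnaire, patient):
        session = _session(questionnaire)
        eng.authenticate(session, patient)
        return session

    def test_skip_raises_mandatory_error(self, live):
        item = eng.next_item(live)
        with pytest.raises(eng.AnswerError) as err:
            eng.record_answer(live, item.link_id, "")
        assert err.value.kind == "mandatory"

    def test_invalid_option_code_is_rejected(self, live):
        item = eng.next_item(live)
        assert item.is_choice
        with pytest.raises(eng.AnswerError) as err:
            eng.record_answer(live, item.link_id, "not-a-code")
        assert err.value.kind == "invalid-option"

    def test_two_values_on_single_choice_is_a_cardinality_error(self, live):
        item = eng.next_item(live)
        assert item.item_type == fm.SINGLE_CHOICE
        codes = [o.code for o in item.options][:2]
        with pytest.raises(eng.AnswerError) as err:
            eng.record_answer(live, item.link_id, codes)
        assert err.value.kind == "cardinality"

    def test_answering_an_item_that_is_not_posed_is_a_state_error(self, live):
        eng.next_item(live)
        with pytest.raises(eng.StateError):
            eng.record_answer(live, "item-99", "x")

    def test_free_text_is_stored_verbatim(self, questionnaire, patient):
        session = _session(questionnaire)
        eng.authenticate(session, patient)
        raw = "  WeIrD   SpAcInG & punctuation!! "
        while (item := eng.next_item(session)) is not None:
            if item.item_type == fm.FREE_TEXT:
                eng.record_answer(session, item.link_id, raw)
                assert session.answers[item.link_id][0].value == raw
                return
            eng.record_answer(session, item.link_id, item.options[0].code)
        pytest.fail("no free-text item reached")


class TestSummaryAndSubmit:
    def _completed(self, questionnaire, seed=11, gender=None):
        script = fx.gen_scripted_session(questionnaire, "random-valid", seed)
        if gender is not None:
            script["answers"][fx.GENDER_LINK_ID] = gender
        return eng.run_scripted_session(
            fx.gen_task(questionnaire), questionnaire, script)

    def test_summary_has_one_entry_per_answered_item_in_order(self, questionnaire):
        session = self._completed(questionnaire)
        summary = eng.build_summary(session)
        assert len(summary.entries) == len(session.answers)
        texts = [e[0] for e in summary.entries]
        expected = [i.text for i in questionnaire.items
                    if i.link_id in session.answers]
        assert texts == expected

    def test_summary_omits_branch_skipped_items(self, questionnaire):
        session = self._completed(questionnaire, gender="male")
        preg_text = questionnaire.item(fx.PREGNANCY_LINK_ID).text
        assert preg_text not in [e[0] for e in eng.build_summary(session).entries]

    def test_summary_requires_confirmation_phase(self, questionnaire, task):
        session = eng.start_session(task, questionnaire)
        with pytest.raises(eng.StateError):
            eng.build_summary(session)

    def test_submit_completes_task_and_validates(self, questionnaire):
        session = self._completed(questionnaire)
        doc, log = eng.submit(session)
        assert session.phase == "submitted"
        assert session.task.status == "completed"
        assert fm.validate_response(doc, questionnaire) == []
        assert len(log) == len(session.transcript)

    def test_double_submission_is_rejected(self, questionnaire):
        session = self._completed(questionnaire)
        eng.submit(session)
        with pytest.raises(eng.StateError):
            eng.submit(session)

    def test_log_contains_one_user_turn_per_answer_and_qa_turns(
            self, questionnaire, kb):
        script = fx.gen_scripted_session(questionnaire, "random-valid", 13)
        script["qa_queries"] = [kb.pairs[0].question, kb.pairs[1].question]
        session = eng.run_scripted_session(
            fx.gen_task(questionnaire), questionnaire, script, kb)
        _, log = eng.submit(session)
        user_turns = [t for t in log if t["speaker"] == "user"]
        # 1 auth + answered items + 2 qa queries
        assert len(user_turns) == 1 + len(session.answers) + 2
        assert len(session.qa_turns) == 2
        lines = eng.transcript_log_lines(log).splitlines()
        assert len(lines) == len(log)
        assert all(json.loads(line)["speaker"] in ("agent", "user")
                   for line in lines)

    def test_conservation_answered_plus_disabled_is_total(self, questionnaire):
        for seed in range(8):
            session = self._completed(questionnaire, seed=seed)
            answered = set(session.answers)
            disabled = {i.link_id for i in questionnaire.answerable_items
                        if i.link_id not in answered}
            for link_id in disabled:
                assert not eng.is_enabled(questionnaire.item(link_id),
                                          session.answers)
            assert len(answered) + len(disabled) == len(questionnaire.answerable_items)

    def test_qa_phase_can_be_ended_with_zero_questions(self, questionnaire):
        session = self._completed(questionnaire)
        assert session.phase == "confirmation"
        assert session.qa_turns == []


class TestClockAndTranscript:
    def test_injected_clock_makes_timestamps_deterministic(self, questionnaire):
        script = fx.gen_scripted_session(questionnaire, "always-first-option", 1)
        runs = []
        for _ in range(2):
            session = eng.run_scripted_session(
                fx.gen_task(questionnaire), questionnaire, script,
                clock=eng.Clock())
            runs.append([(t.speaker, t.text, t.timestamp)
                         for t in session.transcript])
        assert runs[0] == runs[1]

    def test_transcript_turns_strictly_ordered(self, questionnaire):
        script = fx.gen_scripted_session(questionnaire, "random-valid", 4)
        session = eng.run_scripted_session(
            fx.gen_task(questionnaire), questionnaire, script)
        times = [t.timestamp for t in session.transcript]
        assert all(a < b for a, b in zip(times, times[1:]))
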