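"""Session engine: asking, confirming, diagnosing, progress, replay."""

import pytest

from vcase.fixtures import make_case_fixture, simulate_student
from vcase.matching import MatchOutcome
from vcase.session import (
    ActionLog,
    SessionScene,
    analyze_progress,
    ask,
    confirm_candidate,
    enter_free_text,
    finish,
    replay,
    select_items,
    start_session,
    submit_diagnosis,
    switch_scene,
)


@pytest.fixture()
def session(hernia_fixture):
    return start_session(
        hernia_fixture.playable, "stu-1", hernia_fixture.pipeline
    )


def consultation_question(fx):
    return next(
        q for q in fx.library if q.scene.value == "consultation"
    )


class TestLifecycle:
    def test_fresh_session_is_empty(self, session):
        assert all(not sel for sel in session.selections.values())
        assert session.current_scene is SessionScene.CONSULTATION
        assert not session.finished

    def test_unreleased_case_rejected(self, hernia_fixture):
        draft = hernia_fixture.playable.model_copy(deep=True)
        draft.base.review_status = "draft"
        with pytest.raises(ValueError):
            start_session(draft, "stu", hernia_fixture.pipeline)

    def test_sessions_are_independent(self, hernia_fixture):
        fx = hernia_fixture
        a = start_session(fx.playable, "s1", fx.pipeline)
        b = start_session(fx.playable, "s2", fx.pipeline)
        ask(a, consultation_question(fx).display_text)
        assert b.selections["inquiries"] == {}

    def test_double_finish_rejected(self, session):
        finish(session)
        with pytest.raises(ValueError):
            finish(session)

    def test_finish_immediately_yields_valid_log(self, session):
        log = finish(session)
        assert log.events[0].kind == "start"
        assert log.events[-1].kind == "finish"


class TestAsk:
    def test_exact_question_collects_and_answers(self, hernia_fixture, session):
        q = consultation_question(hernia_fixture)
        case_q = hernia_fixture.playable.question_by_id(q.question_id)
        res = ask(session, q.display_text)
        assert res.outcome is MatchOutcome.EXACT
        assert res.matched.answer_text == case_q.answer_text
        assert session.selections["inquiries"][q.question_id] is True

    def test_deviation_logged_with_verbatim_message(self, session):
        res = ask(session, "zzzzzzzzzzzzzzzz")
        assert res.outcome is MatchOutcome.DEVIATED
        assert res.message == "You have deviated from the correct process"
        assert session.selections["inquiries"] == {}

    def test_ask_twice_is_idempotent(self, hernia_fixture, session):
        q = consultation_question(hernia_fixture)
        ask(session, q.display_text)
        first = dict(session.selections["inquiries"])
        res = ask(session, q.display_text)
        case_q = hernia_fixture.playable.question_by_id(q.question_id)
        assert res.matched.answer_text == case_q.answer_text
        assert session.selections["inquiries"] == first

    def test_ask_rejected_after_finish(self, hernia_fixture, session):
        finish(session)
        with pytest.raises(ValueError):
            ask(session, consultation_question(hernia_fixture).display_text)

    def test_ask_rejected_in_diagnosis_scene(self, hernia_fixture, session):
        switch_scene(session, SessionScene.DIAGNOSIS)
        with pytest.raises(ValueError):
            ask(session, consultation_question(hernia_fixture).display_text)


class TestConfirmCandidate:
    def _near_miss(self, fx):
        q = consultation_question(fx)
        # perturb one token so distance is 1: candidate set, not exact
        toks = list(q.canonical_tokens)
        toks[0] = "zzz"
        return q, "".join(toks)

    def test_confirm_collects(self, hernia_fixture, session):
        q, text = self._near_miss(hernia_fixture)
        res = ask(session, text)
        assert res.outcome is MatchOutcome.CANDIDATES
        assert q.question_id in [c.question_id for c, _d in res.candidates]
        answer = confirm_candidate(session, res.candidates[0][0].question_id)
        assert answer == res.candidates[0][0].answer_text
        assert session.selections["inquiries"]

    def test_confirm_non_candidate_rejected(self, hernia_fixture, session):
        _q, text = self._near_miss(hernia_fixture)
        ask(session, text)
        with pytest.raises(ValueError):
            confirm_candidate(session, "not-a-candidate")

    def test_no_state_change_until_confirm(self, hernia_fixture, session):
        _q, text = self._near_miss(hernia_fixture)
        ask(session, text)
        assert session.selections["inquiries"] == {}


class TestSubmitDiagnosis:
    def test_correct_diagnosis_accepted(self, session):
        switch_scene(session, SessionScene.DIAGNOSIS)
        assert submit_diagnosis(session, "Right inguinal hernia") is True
        assert session.selections["diagnoses"]["dx-K40.9"] is True

    def test_wrong_diagnosis_recorded_as_error(self, session):
        switch_scene(session, SessionScene.DIAGNOSIS)
        assert submit_diagnosis(session, "Lipoma in the groin area") is False
        assert "Lipoma in the groin area" in session.error_diagnoses

    def test_match_by_icd_code(self, session):
        switch_scene(session, SessionScene.DIAGNOSIS)
        assert submit_diagnosis(session, "K40.9") is True

    def test_empty_text_rejected(self, session):
        switch_scene(session, SessionScene.DIAGNOSIS)
        with pytest.raises(ValueError):
            submit_diagnosis(session, "   ")


class TestSelectAndFreeEntry:
    def test_correct_bases_flagged_correct(self, hernia_fixture, session):
        ids = [b.item_id for b in hernia_fixture.case.diagnosis_bases]
        select_items(session, "bases", ids)
        flags = session.selections["bases"]
        for b in hernia_fixture.case.diagnosis_bases:
            assert flags[b.item_id] == b.is_correct

    def test_distractor_treatment_flagged_incorrect(self, hernia_fixture, session):
        wrong = next(
            t for t in hernia_fixture.case.treatments if not t.is_correct
        )
        select_items(session, "treatments", [wrong.item_id])
        assert session.selections["treatments"][wrong.item_id] is False

    def test_unknown_id_rejected(self, session):
        with pytest.raises(KeyError):
            select_items(session, "bases", ["no-such-item"])

    def test_reselect_no_duplicate(self, hernia_fixture, session):
        bid = hernia_fixture.case.diagnosis_bases[0].item_id
        select_items(session, "bases", [bid])
        select_items(session, "bases", [bid])
        assert list(session.selections["bases"]) == [bid]

    def test_free_entry_graded_by_text(self, hernia_fixture, session):
        basis = hernia_fixture.case.diagnosis_bases[0]
        assert enter_free_text(session, "bases", basis.text.upper()) is True
        assert enter_free_text(session, "bases", "made up basis") is False
        assert ("bases", "made up basis") in session.free_entry_misses


class TestAnalyzeProgress:
    def test_nothing_collected_all_important_missing(self, session):
        analysis = analyze_progress(session, importance_cutoff=0.0)
        assert analysis.collected_factors == []
        assert analysis.missing_important  # every item missing

    def test_everything_collected_missing_empty(self, hernia_fixture):
        _t, session = simulate_student(hernia_fixture, 1.0, seed=0)
        analysis = analyze_progress(session)
        assert analysis.missing_important == []
        assert analysis.hypotheses

    def test_cutoff_above_max_weight_missing_empty(self, session):
        analysis = analyze_progress(session, importance_cutoff=1e9)
        assert analysis.missing_important == []

    def test_disjoint_invariant(self, hernia_fixture):
        _t, session = simulate_student(hernia_fixture, 0.5, seed=9)
        analysis = analyze_progress(session)
        assert not set(analysis.missing_important) & set(
            analysis.collected_factors
        )


class TestReplay:
    @pytest.mark.parametrize("competence", [0.0, 0.3, 0.7, 1.0])
    def test_replay_reconstructs_state(self, hernia_fixture, competence):
        trace, session = simulate_student(
            hernia_fixture, competence, seed=int(competence * 100)
        )
        rebuilt = replay(trace.actions, hernia_fixture.playable, hernia_fixture.pipeline)
        assert rebuilt.snapshot() == session.snapshot()

    def test_log_round_trips_through_jsonl(self, hernia_fixture):
        trace, session = simulate_student(hernia_fixture, 0.6, seed=5)
        text = trace.actions.to_jsonl()
        log = ActionLog.from_jsonl(text)
        assert log == trace.actions
        rebuilt = replay(log, hernia_fixture.playable, hernia_fixture.pipeline)
        assert rebuilt.snapshot() == session.snapshot()

    def test_scene_switching_preserves_selections(self, hernia_fixture, session):
        q = consultation_question(hernia_fixture)
        ask(session, q.display_text)
        switch_scene(session, SessionScene.PHYSICAL_EXAM)
        switch_scene(session, SessionScene.DIAGNOSIS)
        switch_scene(session, SessionScene.CONSULTATION)
        assert session.selections["inquiries"][q.question_id] is True

    def test_timestamps_monotone(self, hernia_fixture):
        trace, _ = simulate_student(hernia_fixture, 0.8, seed=2)
        times = [e.time for e in trace.actions.events]
        assert times == sorted(times)
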