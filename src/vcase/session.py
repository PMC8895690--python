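"""Double-cycle learning sessions over a playable case.

A session walks the information-collection scenes (consultation, physical
examination, auxiliary examination), then diagnosis, basis and treatment
selection, with inner-loop feedback after every action. Every action is
appended to an event log; replaying the log through the same pipeline
reconstructs the final state exactly, which is what makes scoring and
review auditable.
"""

from __future__ import annotations

import json
import uuid
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .casebuilder import PlayableCase, ReviewStatus
from .matching import (
    MatchOutcome,
    MatchResult,
    NlpPipeline,
    QuestionLibrary,
    Scene,
    match_question,
)

__all__ = [
    "SessionScene",
    "SessionEvent",
    "ActionLog",
    "SessionState",
    "ProgressAnalysis",
    "start_session",
    "switch_scene",
    "ask",
    "confirm_candidate",
    "submit_diagnosis",
    "select_items",
    "enter_free_text",
    "analyze_progress",
    "finish",
    "replay",
]


class SessionScene(str, Enum):
    CONSULTATION = "consultation"
    PHYSICAL_EXAM = "physical_exam"
    AUXILIARY_EXAM = "auxiliary_exam"
    DIAGNOSIS = "diagnosis"
    TREATMENT = "treatment"


_QUESTION_SCENES = {
    SessionScene.CONSULTATION: Scene.CONSULTATION,
    SessionScene.PHYSICAL_EXAM: Scene.PHYSICAL_EXAM,
    SessionScene.AUXILIARY_EXAM: Scene.AUXILIARY_EXAM,
}

# scene -> scoring category for collected question items; auxiliary
# examinations are scored with the physical examinations.
SCENE_CATEGORY = {
    SessionScene.CONSULTATION: "inquiries",
    SessionScene.PHYSICAL_EXAM: "physical_exams",
    SessionScene.AUXILIARY_EXAM: "physical_exams",
}


class SessionEvent(BaseModel):
    """One append-only log entry: (time, scene, action kind, payload)."""

    time: float
    scene: SessionScene
    kind: str
    payload: dict = Field(default_factory=dict)


class ActionLog(BaseModel):
    """Replayable event stream of one learning session."""

    session_id: str
    student_id: str
    case_id: str
    level: int
    events: list[SessionEvent]

    def to_jsonl(self) -> str:
        header = json.dumps(
            {
                "session_id": self.session_id,
                "student_id": self.student_id,
                "case_id": self.case_id,
                "level": self.level,
            },
            ensure_ascii=False,
        )
        lines = [header] + [
            json.dumps(e.model_dump(mode="json"), ensure_ascii=False)
            for e in self.events
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "ActionLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = json.loads(lines[0])
        events = [SessionEvent(**json.loads(ln)) for ln in lines[1:]]
        return cls(events=events, **head)


class SessionState:
    """Mutable state of one session; every mutation goes through the log."""

    def __init__(
        self,
        case: PlayableCase,
        student_id: str,
        pipeline: NlpPipeline,
        session_id: str | None = None,
        start_time: float = 0.0,
    ) -> None:
        self.session_id = session_id or str(uuid.uuid4())
        self.case = case
        self.student_id = student_id
        self.pipeline = pipeline
        self.current_scene = SessionScene.CONSULTATION
        self.asked: list[tuple[str, str, str | None, float]] = []
        # category -> {item_id: correct?}
        self.selections: dict[str, dict[str, bool]] = {
            "inquiries": {},
            "physical_exams": {},
            "diagnoses": {},
            "bases": {},
            "treatments": {},
        }
        self.error_diagnoses: list[str] = []
        self.free_entry_misses: list[tuple[str, str]] = []
        self.pending_candidates: list[str] = []
        self.start_time = start_time
        self.end_time: float | None = None
        self.events: list[SessionEvent] = []
        self._clock = start_time

    # -- internal helpers ---------------------------------------------------

    @property
    def finished(self) -> bool:
        return self.end_time is not None

    def _tick(self, at: float | None) -> float:
        t = self._clock + 1.0 if at is None else float(at)
        if t < self._clock:
            raise ValueError("timestamps must be monotone")
        self._clock = t
        return t

    def _log(self, t: float, kind: str, payload: dict) -> None:
        self.events.append(
            SessionEvent(time=t, scene=self.current_scene, kind=kind, payload=payload)
        )

    def _require_active(self) -> None:
        if self.finished:
            raise ValueError("session already finished")

    def snapshot(self) -> dict:
        """Comparable view of the full state (replay-equivalence checks)."""
        return {
            "session_id": self.session_id,
            "student_id": self.student_id,
            "case_id": self.case.base.case_id,
            "scene": self.current_scene.value,
            "asked": list(self.asked),
            "selections": {k: dict(sorted(v.items())) for k, v in self.selections.items()},
            "error_diagnoses": list(self.error_diagnoses),
            "free_entry_misses": list(self.free_entry_misses),
            "start_time": self.start_time,
            "end_time": self.end_time,
        }


class ProgressAnalysis(BaseModel):
    """Diagnostic factors and hypotheses so far, plus important gaps."""

    collected_factors: list[str]
    hypotheses: list[str]
    missing_important: list[str]


# ---------------------------------------------------------------------------
# Session operations
# ---------------------------------------------------------------------------


def start_session(
    case: PlayableCase,
    student_id: str,
    pipeline: NlpPipeline,
    *,
    session_id: str | None = None,
    start_time: float = 0.0,
) -> SessionState:
    """Open a session on a released playable case, starting in consultation."""
    if case.base.review_status is not ReviewStatus.RELEASED:
        raise ValueError("cannot start a session on an unreleased case")
    s = SessionState(
        case, student_id, pipeline, session_id=session_id, start_time=start_time
    )
    s._log(start_time, "start", {"student_id": student_id, "level": case.level})
    return s


def switch_scene(
    session: SessionState, scene: SessionScene, at: float | None = None
) -> None:
    """Move to another scene; selections are never lost on switching."""
    session._require_active()
    t = session._tick(at)
    session.current_scene = SessionScene(scene)
    session._log(t, "switch_scene", {"scene": session.current_scene.value})


def _scene_library(session: SessionState) -> QuestionLibrary:
    scene = _QUESTION_SCENES[session.current_scene]
    return QuestionLibrary(questions=session.case.questions_for_scene(scene))


def ask(session: SessionState, text: str, at: float | None = None) -> MatchResult:
    """Ask a free-text question in the current collection scene.

    An exact match returns the answer and marks the item collected (set
    semantics: re-asking changes nothing); a candidate set is held pending
    until the student reconfirms; a deviation is logged with the standard
    message and collects nothing.
    """
    session._require_active()
    if session.current_scene not in _QUESTION_SCENES:
        raise ValueError(
            f"scene {session.current_scene.value!r} does not take questions"
        )
    lib = _scene_library(session)
    if len(lib) == 0:
        raise ValueError(f"case has no {session.current_scene.value} questions")
    t = session._tick(at)
    result = match_question(text, lib, session.pipeline)
    matched_id = result.matched.question_id if result.matched else None
    session.asked.append((text, result.outcome.value, matched_id, t))
    session._log(t, "ask", {"text": text})
    if result.outcome is MatchOutcome.EXACT:
        q = result.matched
        assert q is not None
        session.selections[SCENE_CATEGORY[session.current_scene]][
            q.question_id
        ] = q.is_correct_item
        session.pending_candidates = []
    elif result.outcome is MatchOutcome.CANDIDATES:
        session.pending_candidates = [q.question_id for q, _d in result.candidates]
    else:
        session.pending_candidates = []
    return result


def confirm_candidate(
    session: SessionState, question_id: str, at: float | None = None
) -> str:
    """Reconfirm one question from the pending candidate set; returns its answer."""
    session._require_active()
    if question_id not in session.pending_candidates:
        raise ValueError(f"{question_id!r} is not a pending candidate")
    t = session._tick(at)
    q = session.case.question_by_id(question_id)
    session.selections[SCENE_CATEGORY[session.current_scene]][
        q.question_id
    ] = q.is_correct_item
    session.pending_candidates = []
    session._log(t, "confirm", {"question_id": question_id})
    return q.answer_text


def _normalize_label(text: str) -> str:
    return " ".join(text.casefold().split())


def submit_diagnosis(
    session: SessionState, text: str, at: float | None = None
) -> bool:
    """Submit a diagnosis; correct iff it matches the case's ICD reference list.

    A correct diagnosis (by label or ICD code) joins the student's
    differential; anything else is recorded as an error diagnosis for the
    teacher's error report.
    """
    session._require_active()
    if session.current_scene is not SessionScene.DIAGNOSIS:
        raise ValueError("diagnoses are submitted in the diagnosis scene")
    if not text or not text.strip():
        raise ValueError("diagnosis text must be non-empty")
    t = session._tick(at)
    session._log(t, "diagnosis", {"text": text})
    norm = _normalize_label(text)
    for d in session.case.base.diagnoses:
        if norm in (_normalize_label(d.label), _normalize_label(d.icd_code)):
            session.selections["diagnoses"][f"dx-{d.icd_code}"] = d.is_correct
            if not d.is_correct and d.label not in session.error_diagnoses:
                session.error_diagnoses.append(d.label)
            return d.is_correct
    if text not in session.error_diagnoses:
        session.error_diagnoses.append(text)
    return False


def select_items(
    session: SessionState,
    category: str,
    ids: Iterable[str],
    at: float | None = None,
) -> None:
    """Select diagnosis bases or treatments by id (set semantics)."""
    session._require_active()
    if category not in ("bases", "treatments"):
        raise ValueError("category must be 'bases' or 'treatments'")
    pool = (
        session.case.base.diagnosis_bases
        if category == "bases"
        else session.case.base.treatments
    )
    by_id = {item.item_id: item for item in pool}
    ids = list(ids)
    for item_id in ids:
        if item_id not in by_id:
            raise KeyError(f"unknown {category} id {item_id!r}")
    t = session._tick(at)
    for item_id in ids:
        session.selections[category][item_id] = by_id[item_id].is_correct
    session._log(t, "select", {"category": category, "ids": sorted(ids)})


def enter_free_text(
    session: SessionState,
    category: str,
    text: str,
    at: float | None = None,
) -> bool:
    """Free-entry of a basis or treatment at levels 3-4, graded against ground truth."""
    session._require_active()
    if category not in ("bases", "treatments"):
        raise ValueError("category must be 'bases' or 'treatments'")
    pool = (
        session.case.base.diagnosis_bases
        if category == "bases"
        else session.case.base.treatments
    )
    t = session._tick(at)
    session._log(t, "free_entry", {"category": category, "text": text})
    norm = _normalize_label(text)
    for item in pool:
        if norm == _normalize_label(item.text):
            session.selections[category][item.item_id] = item.is_correct
            return item.is_correct
    session.free_entry_misses.append((category, text))
    return False


def analyze_progress(
    session: SessionState,
    importance_cutoff: float | None = None,
    importance_quantile: float = 0.75,
) -> ProgressAnalysis:
    """List collected factors, hypotheses, and important items still missing.

    The importance cutoff defaults to the given quantile (75th percentile)
    of the case's correct-item score weights.
    """
    case = session.case.base
    weights: dict[str, float] = {}
    for q in session.case.questions:
        if q.is_correct_item:
            weights[q.question_id] = q.score_weight
    for d in case.diagnoses:
        if d.is_correct:
            weights[f"dx-{d.icd_code}"] = d.score_weight
    for item in (*case.diagnosis_bases, *case.treatments):
        if item.is_correct:
            weights[item.item_id] = item.score_weight
    if importance_cutoff is None:
        importance_cutoff = float(
            np.quantile(list(weights.values()), importance_quantile)
        )
    collected = sorted(
        item_id
        for sel in session.selections.values()
        for item_id, ok in sel.items()
        if ok
    )
    hypotheses = sorted(
        item_id for item_id, ok in session.selections["diagnoses"].items() if ok
    )
    missing = sorted(
        item_id
        for item_id, w in weights.items()
        if w >= importance_cutoff and item_id not in collected
    )
    return ProgressAnalysis(
        collected_factors=collected,
        hypotheses=hypotheses,
        missing_important=missing,
    )


def finish(session: SessionState, at: float | None = None) -> ActionLog:
    """Close the session and return its replayable log."""
    session._require_active()
    t = session._tick(at)
    session.end_time = t
    session._log(t, "finish", {})
    return ActionLog(
        session_id=session.session_id,
        student_id=session.student_id,
        case_id=session.case.base.case_id,
        level=session.case.level,
        events=list(session.events),
    )


def replay(log: ActionLog, case: PlayableCase, pipeline: NlpPipeline) -> SessionState:
    """Reconstruct a session state from its log, event by event.

    With the same case and pipeline, the reconstructed snapshot is
    identical to the one at finish time.
    """
    events = log.events
    if not events or events[0].kind != "start":
        raise ValueError("log must begin with a start event")
    s = start_session(
        case,
        log.student_id,
        pipeline,
        session_id=log.session_id,
        start_time=events[0].time,
    )
    for e in events[1:]:
        if e.kind == "switch_scene":
            switch_scene(s, SessionScene(e.payload["scene"]), at=e.time)
        elif e.kind == "ask":
            ask(s, e.payload["text"], at=e.time)
        elif e.kind == "confirm":
            confirm_candidate(s, e.payload["question_id"], at=e.time)
        elif e.kind == "diagnosis":
            submit_diagnosis(s, e.payload["text"], at=e.time)
        elif e.kind == "select":
            select_items(s, e.payload["category"], e.payload["ids"], at=e.time)
        elif e.kind == "free_entry":
            enter_free_text(s, e.payload["category"], e.payload["text"], at=e.time)
        elif e.kind == "finish":
            finish(s, at=e.time)
        else:
            raise ValueError(f"unknown event kind {e.kind!r}")
    return s
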