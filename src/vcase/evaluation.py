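"""Clinical-thinking scoring: the five rubric indicators and feedback report.

A finished session is reduced to counting inputs and scored on five
indicators, each on a 0-100 scale:

* rigor        — 100 x (correct-diagnosis bases selected / all such bases)
* logic        — 100 x (inquiries selected - inquiries missed + physical
                 exams selected - physical exams missed) / (correct
                 inquiries + correct physical exams), clamped to [0, 100]
* systematic   — 100 x (correct selections / correct items) over inquiries,
                 physical exams, diagnoses, bases and treatments together
* agility      — 100 x (4 T_rec / (4 T_rec + T_act)) x (selected score /
                 total score)
* expansion    — 100 x (selected diagnosis+basis score / total
                 diagnosis+basis score)

The written logic formula can go negative when misses outnumber hits
(interpreting its first term as correct-inquiries-selected); the score is
clamped at zero so every indicator stays within [0, 100]. A category with
no correct items at all is scored 100 (vacuously complete) and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from pydantic import BaseModel, Field

from .session import SessionState

__all__ = [
    "ScoreInputs",
    "ErrorDiagnosisRecord",
    "EvaluationReport",
    "score_rigor",
    "score_logic",
    "score_systematic",
    "score_agility",
    "score_expansion",
    "derive_score_inputs",
    "build_report",
    "RADAR_ORDER",
]

logger = logging.getLogger(__name__)

RADAR_ORDER = ("rigor", "logic", "systematic", "agility", "expansion")


@dataclass
class ScoreInputs:
    """Counting inputs for the five indicators.

    ``missed`` counts are always ``total - selected`` per category; times
    are in seconds; score fields are sums of item score weights.
    """

    n_bases_selected_correct: int = 0
    n_bases_total_correct: int = 0
    n_inq_selected_correct: int = 0
    n_inq_correct_total: int = 0
    n_pe_selected_correct: int = 0
    n_pe_correct_total: int = 0
    n_all_selected_correct: int = 0
    n_all_correct_total: int = 0
    recommended_time: float = 1.0
    actual_time: float = 1.0
    selected_score: float = 0.0
    total_score: float = 0.0
    dx_selected_score: float = 0.0
    dx_total_score: float = 0.0

    @property
    def n_inq_correct_missed(self) -> int:
        return self.n_inq_correct_total - self.n_inq_selected_correct

    @property
    def n_pe_correct_missed(self) -> int:
        return self.n_pe_correct_total - self.n_pe_selected_correct

    def __post_init__(self) -> None:
        if self.recommended_time <= 0:
            raise ValueError("recommended time must be positive")
        if self.actual_time < 0:
            raise ValueError("actual time cannot be negative")
        for name in (
            "n_bases_selected_correct",
            "n_bases_total_correct",
            "n_inq_selected_correct",
            "n_inq_correct_total",
            "n_pe_selected_correct",
            "n_pe_correct_total",
            "n_all_selected_correct",
            "n_all_correct_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} cannot be negative")


def _vacuous(name: str) -> float:
    logger.info("%s has no correct items; scored 100 (vacuous)", name)
    return 100.0


def score_rigor(inputs: ScoreInputs) -> float:
    """Completeness of the bases selected under the correct diagnoses."""
    if inputs.n_bases_total_correct == 0:
        return _vacuous("rigor")
    return 100.0 * inputs.n_bases_selected_correct / inputs.n_bases_total_correct


def score_logic(inputs: ScoreInputs) -> float:
    """Hit-minus-miss balance over inquiries and physical examinations."""
    denom = inputs.n_inq_correct_total + inputs.n_pe_correct_total
    if denom == 0:
        return _vacuous("logic")
    num = (
        inputs.n_inq_selected_correct
        - inputs.n_inq_correct_missed
        + inputs.n_pe_selected_correct
        - inputs.n_pe_correct_missed
    )
    return min(100.0, 100.0 * max(0, num) / denom)


def score_systematic(inputs: ScoreInputs) -> float:
    """Overall correct-selection rate across all five item categories."""
    if inputs.n_all_correct_total == 0:
        return _vacuous("systematic")
    return 100.0 * inputs.n_all_selected_correct / inputs.n_all_correct_total


def score_agility(inputs: ScoreInputs) -> float:
    """Speed-weighted score rate; decreasing in time, increasing in score."""
    if inputs.total_score <= 0:
        raise ValueError("total score must be positive for agility")
    time_factor = (4.0 * inputs.recommended_time) / (
        4.0 * inputs.recommended_time + inputs.actual_time
    )
    return 100.0 * time_factor * (inputs.selected_score / inputs.total_score)


def score_expansion(inputs: ScoreInputs) -> float:
    """Score-weighted accuracy of diagnoses and their bases."""
    if inputs.dx_total_score == 0:
        return _vacuous("expansion")
    return 100.0 * inputs.dx_selected_score / inputs.dx_total_score


class ErrorDiagnosisRecord(BaseModel):
    """One row of the teacher-facing error-diagnosis table."""

    case_id: str
    discipline: str
    disease: str
    overview: str
    learning_times: int = 1
    student_name: str = ""
    student_type: str = ""
    correct_selected: list[str] = Field(default_factory=list)
    error_selected: list[str] = Field(default_factory=list)


class EvaluationReport(BaseModel):
    """Five indicators, total, radar payload and teacher feedback."""

    rigor: float = Field(ge=0.0, le=100.0)
    logic: float = Field(ge=0.0, le=100.0)
    systematic: float = Field(ge=0.0, le=100.0)
    agility: float = Field(ge=0.0, le=100.0)
    expansion: float = Field(ge=0.0, le=100.0)
    total: float = Field(ge=0.0, le=100.0)
    radar: list[float]
    error_diagnoses: list[ErrorDiagnosisRecord] = Field(default_factory=list)
    missing_items: list[str] = Field(default_factory=list)

    def to_json(self) -> str:
        return self.model_dump_json(indent=1)


def derive_score_inputs(session: SessionState) -> ScoreInputs:
    """Reduce a finished session plus case ground truth to scoring counts."""
    if not session.finished:
        raise ValueError("session must be finished before scoring")
    case = session.case.base
    questions = session.case.questions

    inq_total = [
        q for q in questions
        if q.scene.value == "consultation" and q.is_correct_item
    ]
    pe_total = [
        q for q in questions
        if q.scene.value in ("physical_exam", "auxiliary_exam") and q.is_correct_item
    ]
    dx_total = [d for d in case.diagnoses if d.is_correct]
    bases_total = [b for b in case.diagnosis_bases if b.is_correct]
    tx_total = [t for t in case.treatments if t.is_correct]

    sel = session.selections
    inq_sel = [q for q in inq_total if sel["inquiries"].get(q.question_id)]
    pe_sel = [q for q in pe_total if sel["physical_exams"].get(q.question_id)]
    dx_sel = [d for d in dx_total if sel["diagnoses"].get(f"dx-{d.icd_code}")]
    bases_sel = [b for b in bases_total if sel["bases"].get(b.item_id)]
    tx_sel = [t for t in tx_total if sel["treatments"].get(t.item_id)]

    def wsum(items) -> float:
        return float(sum(i.score_weight for i in items))

    total_score = (
        wsum(inq_total) + wsum(pe_total) + wsum(dx_total)
        + wsum(bases_total) + wsum(tx_total)
    )
    selected_score = (
        wsum(inq_sel) + wsum(pe_sel) + wsum(dx_sel)
        + wsum(bases_sel) + wsum(tx_sel)
    )
    end = session.end_time if session.end_time is not None else session.start_time
    return ScoreInputs(
        n_bases_selected_correct=len(bases_sel),
        n_bases_total_correct=len(bases_total),
        n_inq_selected_correct=len(inq_sel),
        n_inq_correct_total=len(inq_total),
        n_pe_selected_correct=len(pe_sel),
        n_pe_correct_total=len(pe_total),
        n_all_selected_correct=(
            len(inq_sel) + len(pe_sel) + len(dx_sel) + len(bases_sel) + len(tx_sel)
        ),
        n_all_correct_total=(
            len(inq_total) + len(pe_total) + len(dx_total)
            + len(bases_total) + len(tx_total)
        ),
        recommended_time=case.recommended_completion_time,
        actual_time=max(0.0, end - session.start_time),
        selected_score=selected_score,
        total_score=total_score,
        dx_selected_score=wsum(dx_sel) + wsum(bases_sel),
        dx_total_score=wsum(dx_total) + wsum(bases_total),
    )


def build_report(
    session: SessionState,
    *,
    learning_times: int = 1,
    student_type: str = "Undergraduate",
) -> EvaluationReport:
    """Score a finished session and assemble the full feedback report.

    The total is the unweighted mean of the five indicators; the radar
    payload lists them in the fixed order rigor, logic, systematic,
    agility, expansion. Error-diagnosis records follow the teacher-report
    table shape; missing items come from the importance analysis.
    """
    from .session import analyze_progress

    inputs = derive_score_inputs(session)
    rigor = score_rigor(inputs)
    logic = score_logic(inputs)
    systematic = score_systematic(inputs)
    agility = score_agility(inputs)
    expansion = score_expansion(inputs)
    total = (rigor + logic + systematic + agility + expansion) / 5.0
    case = session.case.base
    correct_selected = sorted(
        d.label
        for d in case.diagnoses
        if d.is_correct and session.selections["diagnoses"].get(f"dx-{d.icd_code}")
    )
    error_records = []
    if session.error_diagnoses or correct_selected:
        error_records.append(
            ErrorDiagnosisRecord(
                case_id=case.case_id,
                discipline=case.discipline,
                disease=case.disease,
                overview=case.overview,
                learning_times=learning_times,
                student_name=session.student_id,
                student_type=student_type,
                correct_selected=correct_selected,
                error_selected=list(session.error_diagnoses),
            )
        )
    analysis = analyze_progress(session)
    return EvaluationReport(
        rigor=rigor,
        logic=logic,
        systematic=systematic,
        agility=agility,
        expansion=expansion,
        total=total,
        radar=[rigor, logic, systematic, agility, expansion],
        error_diagnoses=error_records,
        missing_items=analysis.missing_important,
    )


def plot_radar(report: EvaluationReport, path: str) -> None:
    """Render the five-indicator radar chart to an image file."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = report.radar + report.radar[:1]
    angles = [
        2 * math.pi * i / len(RADAR_ORDER) for i in range(len(RADAR_ORDER))
    ]
    angles += angles[:1]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(angles, values, "o-", linewidth=1.5)
    ax.fill(angles, values, alpha=0.25)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels([n.capitalize() for n in RADAR_ORDER])
    ax.set_ylim(0, 100)
    ax.set_title(f"Clinical thinking profile (total {report.total:.1f})")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
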