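"""Building reviewable, de-identified, difficulty-graded virtual cases.

The pipeline from source record to released case follows the extraction
workflow of a virtual-patient authoring system: compute each record's
matching rate against the standard question library, rank records and gate
at a review threshold (default 90% coverage), mask personal identifiers
irreversibly with a ``*`` symbol, and derive level-1..4 playable variants
(guided, distractor-injected, partial free-entry, fully independent).
"""

from __future__ import annotations

import math
import warnings
from enum import Enum
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .matching import (
    NlpPipeline,
    QuestionLibrary,
    Scene,
    StandardQuestion,
    edit_distance,
)
from .records import Diagnosis, ScoredItem, SourceRecord, DEFAULT_PII_FIELDS

__all__ = [
    "ReviewStatus",
    "DifficultyClass",
    "VirtualCase",
    "DeidConfig",
    "PlayableCase",
    "compute_matching_rate",
    "rank_and_gate",
    "deidentify",
    "leak_scan",
    "build_virtual_case",
    "apply_difficulty",
    "review_action",
    "MATCHING_RATE_GATE",
]

MATCHING_RATE_GATE = 0.90


class ReviewStatus(str, Enum):
    DRAFT = "draft"
    UNDER_REVIEW = "under_review"
    RELEASED = "released"


class DifficultyClass(str, Enum):
    SIMPLE = "simple"
    MODERATELY_DIFFICULT = "moderately_difficult"
    COMPLEX = "complex"


class VirtualCase(BaseModel):
    """A question-and-answer virtual case assembled from a source record.

    ``source_pii_values`` holds the original identifier values for the
    release-time leak scan only; it is excluded from serialisation so a
    stored case never carries them.
    """

    case_id: str
    discipline: str
    disease: str
    overview: str
    difficulty_class: DifficultyClass = DifficultyClass.SIMPLE
    questions: list[StandardQuestion] = Field(default_factory=list)
    reports: dict[str, str] = Field(default_factory=dict)
    diagnoses: list[Diagnosis] = Field(default_factory=list)
    diagnosis_bases: list[ScoredItem] = Field(default_factory=list)
    treatments: list[ScoredItem] = Field(default_factory=list)
    recommended_completion_time: float = Field(gt=0.0)
    review_status: ReviewStatus = ReviewStatus.DRAFT
    source_pii_values: list[str] = Field(default_factory=list, exclude=True)

    def question_by_id(self, question_id: str) -> StandardQuestion:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)

    def questions_for_scene(self, scene: Scene) -> list[StandardQuestion]:
        return [q for q in self.questions if q.scene == scene]

    def correct_diagnoses(self) -> list[Diagnosis]:
        return [d for d in self.diagnoses if d.is_correct]

    def text_fields(self) -> list[str]:
        """Every human-readable string in the case (leak-scan surface)."""
        out = [self.overview, self.discipline, self.disease]
        for q in self.questions:
            out.extend([q.display_text, q.answer_text, *q.canonical_tokens])
        out.extend(self.reports.values())
        for d in self.diagnoses:
            out.append(d.label)
        for item in (*self.diagnosis_bases, *self.treatments):
            out.append(item.text)
        return out


class DeidConfig(BaseModel):
    """Which structured fields to mask and with what symbol."""

    default_fields: tuple[str, ...] = DEFAULT_PII_FIELDS
    custom_fields: tuple[str, ...] = ()
    mask_symbol: str = "*"

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.default_fields + self.custom_fields))


class PlayableCase(BaseModel):
    """A difficulty-graded view of a released case.

    Level 1 shows the full case with answer references; level 2 injects
    seeded distractor items into the examination scenes; level 3 turns the
    top-weighted scoring items into free-entry; level 4 is fully
    independent (every scoring item free-entry, answers hidden).
    """

    base: VirtualCase
    level: int = Field(ge=1, le=4)
    visible_answers: bool
    distractors: list[StandardQuestion] = Field(default_factory=list)
    free_entry_items: list[str] = Field(default_factory=list)

    @property
    def questions(self) -> list[StandardQuestion]:
        return list(self.base.questions) + list(self.distractors)

    def questions_for_scene(self, scene: Scene) -> list[StandardQuestion]:
        return [q for q in self.questions if q.scene == scene]

    def question_by_id(self, question_id: str) -> StandardQuestion:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)


# ---------------------------------------------------------------------------
# Matching rate and review gate
# ---------------------------------------------------------------------------


def compute_matching_rate(
    record: SourceRecord,
    library: QuestionLibrary,
    pipeline: NlpPipeline,
) -> float:
    """Fraction of standard questions answerable from the record narrative.

    A question counts as answerable when some narrative clause, normalised
    by the segmentation + synonym pipeline, comes within the candidate
    edit-distance cutoff of its canonical tokens.
    """
    if len(library) == 0:
        raise ValueError("question library must be non-empty")
    clauses = record.narrative_clauses()
    if not clauses:
        return 0.0
    normalized = [pipeline.normalize(c)[0] for c in clauses if c]
    matched = 0
    for q in library:
        best = min(
            edit_distance(tokens, q.canonical_tokens) for tokens in normalized
        )
        if best < pipeline.candidate_cutoff:
            matched += 1
    return matched / len(library)


def rank_and_gate(
    records: Sequence[SourceRecord],
    library: QuestionLibrary,
    pipeline: NlpPipeline,
    threshold: float = MATCHING_RATE_GATE,
) -> list[tuple[SourceRecord, float, bool]]:
    """Rank records by matching rate, flagging those at or above the gate.

    Descending by rate; ties broken by record_id, so the ordering is a pure
    function of the record set (permutation invariant).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    scored = [
        (r, compute_matching_rate(r, library, pipeline)) for r in records
    ]
    scored.sort(key=lambda rr: (-rr[1], rr[0].record_id))
    return [(r, rate, rate >= threshold) for r, rate in scored]


# ---------------------------------------------------------------------------
# De-identification
# ---------------------------------------------------------------------------


def deidentify(record: SourceRecord, config: DeidConfig | None = None) -> SourceRecord:
    """Irreversibly mask personal identifiers with the mask symbol.

    Every configured field's value is replaced by a mask of equal length,
    and every occurrence of the original value anywhere in the record —
    other structured fields, narrative sections, the answer manifest — is
    masked too, so the original identity cannot be recovered from the
    output. The PII manifest keeps the field names but drops the values.
    """
    config = config or DeidConfig()
    rec = record.model_copy(deep=True)
    values: list[str] = []
    for fname in config.fields:
        if fname not in rec.structured:
            if fname in config.custom_fields:
                warnings.warn(f"configured field {fname!r} not in record")
            continue
        value = rec.structured[fname]
        if value:
            values.append(value)
            rec.structured[fname] = config.mask_symbol * len(value)

    def scrub(text: str) -> str:
        for v in values:
            text = text.replace(v, config.mask_symbol * len(v))
        return text

    rec.structured = {k: scrub(v) for k, v in rec.structured.items()}
    rec.narrative = {k: scrub(v) for k, v in rec.narrative.items()}
    rec.answer_manifest = {k: scrub(v) for k, v in rec.answer_manifest.items()}
    rec.pii_manifest = {
        k: config.mask_symbol * len(v) for k, v in rec.pii_manifest.items()
    }
    return rec


def leak_scan(case: VirtualCase, pii_values: Sequence[str] | None = None) -> list[str]:
    """Return the PII values that still appear somewhere in the case."""
    values = list(pii_values) if pii_values is not None else case.source_pii_values
    leaks = []
    fields = case.text_fields()
    for v in values:
        if v and any(v in f for f in fields):
            leaks.append(v)
    return leaks


# ---------------------------------------------------------------------------
# Case assembly and difficulty grading
# ---------------------------------------------------------------------------


def build_virtual_case(
    record: SourceRecord,
    library: QuestionLibrary,
    *,
    template,
    case_id: str | None = None,
    difficulty_class: DifficultyClass = DifficultyClass.SIMPLE,
) -> VirtualCase:
    """Assemble a draft virtual case from a (de-identified) record.

    Questions covered by the record's answer manifest get their answer text
    from the matching narrative clause; uncovered questions keep their
    library answer text. Diagnoses, bases, treatments and the recommended
    time come from the disease template.
    """
    questions = []
    for q in library:
        q2 = q.model_copy(deep=True)
        if q.question_id in record.answer_manifest:
            q2.answer_text = record.answer_manifest[q.question_id]
        questions.append(q2)
    return VirtualCase(
        case_id=case_id or f"case-{record.record_id}",
        discipline=template.discipline,
        disease=template.disease,
        overview=template.overview,
        difficulty_class=difficulty_class,
        questions=questions,
        reports={
            k: v
            for k, v in record.structured.items()
            if k.startswith("report_")
        },
        diagnoses=[d.model_copy(deep=True) for d in template.diagnoses],
        diagnosis_bases=[b.model_copy(deep=True) for b in template.bases],
        treatments=[t.model_copy(deep=True) for t in template.treatments],
        recommended_completion_time=template.recommended_time_s,
        source_pii_values=[v for v in record.pii_manifest.values() if v.strip("*")],
    )


def scoring_item_ids(case: VirtualCase) -> list[str]:
    """Ids of every correct (scored) item: questions, diagnoses, bases, treatments."""
    ids = [q.question_id for q in case.questions if q.is_correct_item]
    ids += [f"dx-{d.icd_code}" for d in case.diagnoses if d.is_correct]
    ids += [b.item_id for b in case.diagnosis_bases if b.is_correct]
    ids += [t.item_id for t in case.treatments if t.is_correct]
    return ids


def apply_difficulty(
    case: VirtualCase,
    level: int,
    seed: int,
    *,
    distractor_pool: Sequence[StandardQuestion] = (),
    distractor_fraction: float = 0.30,
    importance_quantile: float = 0.75,
) -> PlayableCase:
    """Derive the playable variant for a learning difficulty level.

    Level 1 keeps the full case with visible answer references and no
    interference. Level 2 injects ``ceil(fraction x n_questions)``
    distractor questions sampled (seeded) from a cross-case pool, flagged
    not-indicated. Level 3 converts scoring items at or above the
    importance quantile of score weights to free entry. Level 4 makes every
    scoring item free entry. Distractor injection never alters the
    correctness flags of original items.
    """
    if case.review_status is not ReviewStatus.RELEASED:
        raise ValueError("case must be released before play")
    if level not in (1, 2, 3, 4):
        raise ValueError(f"invalid level {level}; must be 1-4")
    if level == 1:
        return PlayableCase(base=case, level=1, visible_answers=True)
    if level == 2:
        n = math.ceil(distractor_fraction * len(case.questions))
        if n > 0 and not distractor_pool:
            raise ValueError("level 2 requires a distractor pool")
        rng = np.random.default_rng(seed)
        pool = sorted(distractor_pool, key=lambda q: q.question_id)
        pick = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        distractors = []
        for i in sorted(int(x) for x in pick):
            d = pool[i].model_copy(deep=True)
            d.is_correct_item = False
            d.score_weight = 0.0
            d.question_id = f"distractor-{d.question_id}"
            distractors.append(d)
        return PlayableCase(
            base=case, level=2, visible_answers=False, distractors=distractors
        )
    weights = {
        **{
            q.question_id: q.score_weight
            for q in case.questions
            if q.is_correct_item
        },
        **{f"dx-{d.icd_code}": d.score_weight for d in case.diagnoses if d.is_correct},
        **{b.item_id: b.score_weight for b in case.diagnosis_bases if b.is_correct},
        **{t.item_id: t.score_weight for t in case.treatments if t.is_correct},
    }
    if level == 3:
        cutoff = float(np.quantile(list(weights.values()), importance_quantile))
        free = sorted(i for i, w in weights.items() if w >= cutoff)
        return PlayableCase(
            base=case, level=3, visible_answers=False, free_entry_items=free
        )
    return PlayableCase(
        base=case,
        level=4,
        visible_answers=False,
        free_entry_items=sorted(weights),
    )


# ---------------------------------------------------------------------------
# Teacher review state machine
# ---------------------------------------------------------------------------

_EDITABLE = (ReviewStatus.DRAFT, ReviewStatus.UNDER_REVIEW)


def review_action(
    case: VirtualCase,
    action: str,
    *,
    item: StandardQuestion | None = None,
    item_id: str | None = None,
    difficulty: DifficultyClass | None = None,
) -> VirtualCase:
    """Apply one teacher review action, returning a new case.

    The review workflow is a one-way state machine
    draft -> under_review -> released; released cases are immutable and
    release is blocked while the leak scan still finds PII values.
    """
    if action == "release":
        if case.review_status is ReviewStatus.RELEASED:
            raise ValueError("case already released")
        leaks = leak_scan(case)
        if leaks:
            raise ValueError(
                f"release blocked: {len(leaks)} PII value(s) still present"
            )
        out = case.model_copy(deep=True)
        out.review_status = ReviewStatus.RELEASED
        out.source_pii_values = []
        return out
    if case.review_status not in _EDITABLE:
        raise ValueError("released cases cannot be edited")
    out = case.model_copy(deep=True)
    if action == "add_item":
        if item is None:
            raise ValueError("add_item requires an item")
        if any(q.question_id == item.question_id for q in out.questions):
            raise ValueError(f"duplicate question id {item.question_id!r}")
        out.questions.append(item.model_copy(deep=True))
    elif action == "delete_item":
        if item_id is None:
            raise ValueError("delete_item requires item_id")
        before = len(out.questions)
        out.questions = [q for q in out.questions if q.question_id != item_id]
        if len(out.questions) == before:
            raise KeyError(item_id)
    elif action == "set_difficulty":
        if difficulty is None:
            raise ValueError("set_difficulty requires a difficulty class")
        out.difficulty_class = difficulty
    elif action == "submit_for_review":
        out.review_status = ReviewStatus.UNDER_REVIEW
    else:
        raise ValueError(f"unknown review action {action!r}")
    return out
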