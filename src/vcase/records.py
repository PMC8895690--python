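"""Source medical records and disease templates.

A :class:`SourceRecord` models what arrives from a hospital information
system: structured demographic/PII fields plus report tables, free-text
narrative sections, and the reference diagnoses with their ICD codes. A
:class:`DiseaseTemplate` carries the per-disease ground truth a virtual
case is assembled from: the diagnosis/differential list, scored diagnosis
bases and treatments, and the recommended completion time.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

__all__ = [
    "Diagnosis",
    "ScoredItem",
    "SourceRecord",
    "DiseaseTemplate",
    "BUILTIN_TEMPLATES",
    "get_template",
]

# Demographic fields masked by default, following the HIPAA-style
# de-identification convention for direct identifiers.
DEFAULT_PII_FIELDS: tuple[str, ...] = (
    "name",
    "id_number",
    "phone",
    "address",
    "admission_time",
)


class Diagnosis(BaseModel):
    """A diagnosis label with its ICD code and correctness for the case."""

    label: str
    icd_code: str
    is_correct: bool = True
    score_weight: float = Field(default=3.0, ge=0.0)


class ScoredItem(BaseModel):
    """A selectable scoring item (diagnosis basis or treatment)."""

    item_id: str
    text: str
    score_weight: float = Field(default=1.0, ge=0.0)
    is_correct: bool = True
    diagnosis_label: str | None = None  # bases link to a diagnosis


class SourceRecord(BaseModel):
    """One source record: structured fields, narrative, reference diagnoses.

    ``pii_manifest`` flags which structured fields hold personal
    identifiers and their original values; ``answer_manifest`` is generator
    ground truth mapping standard-question ids to the narrative clause that
    answers them (empty for records not produced by the fixture generator).
    """

    record_id: str
    structured: dict[str, str]
    narrative: dict[str, str]
    true_diagnoses: list[Diagnosis]
    pii_manifest: dict[str, str] = Field(default_factory=dict)
    answer_manifest: dict[str, str] = Field(default_factory=dict)
    disease_template: str = ""

    def narrative_clauses(self, delimiters: str = ",，。.;；") -> list[str]:
        """All non-empty clauses across narrative sections."""
        clauses: list[str] = []
        for text in self.narrative.values():
            buf = ""
            for ch in text:
                if ch in delimiters:
                    if buf:
                        clauses.append(buf)
                    buf = ""
                else:
                    buf += ch
            if buf:
                clauses.append(buf)
        return clauses


class DiseaseTemplate(BaseModel):
    """Per-disease ground truth used to assemble a virtual case."""

    template_id: str
    discipline: str
    disease: str
    overview: str
    diagnoses: list[Diagnosis]
    bases: list[ScoredItem]
    treatments: list[ScoredItem]
    recommended_time_s: float = Field(gt=0.0)


def _hernia_template() -> DiseaseTemplate:
    return DiseaseTemplate(
        template_id="inguinal_hernia",
        discipline="General surgery department",
        disease="Inguinal hernia",
        overview=(
            "A mass in the right groin area was found for 2 years "
            "and pain for half a year"
        ),
        diagnoses=[
            Diagnosis(label="Right inguinal hernia", icd_code="K40.9"),
            Diagnosis(
                label="Lipoma in the groin area",
                icd_code="D17.2",
                is_correct=False,
            ),
            Diagnosis(
                label="Femoral hernia", icd_code="K41.9", is_correct=False
            ),
        ],
        bases=[
            ScoredItem(
                item_id="basis-mass",
                text="Reducible mass in the right groin",
                score_weight=3.0,
                diagnosis_label="Right inguinal hernia",
            ),
            ScoredItem(
                item_id="basis-cough",
                text="Mass enlarges on coughing or standing",
                score_weight=2.0,
                diagnosis_label="Right inguinal hernia",
            ),
            ScoredItem(
                item_id="basis-ultrasound",
                text="Ultrasound shows bowel loop in the inguinal canal",
                score_weight=5.0,
                diagnosis_label="Right inguinal hernia",
            ),
            ScoredItem(
                item_id="basis-pain",
                text="Local dull pain for half a year",
                score_weight=2.0,
                diagnosis_label="Right inguinal hernia",
            ),
        ],
        treatments=[
            ScoredItem(
                item_id="tx-repair",
                text="Elective tension-free hernia repair",
                score_weight=5.0,
            ),
            ScoredItem(
                item_id="tx-observe",
                text="Immediate emergency laparotomy",
                score_weight=2.0,
                is_correct=False,
            ),
        ],
        recommended_time_s=1200.0,
    )


def _ugi_template() -> DiseaseTemplate:
    return DiseaseTemplate(
        template_id="ugi_hemorrhage",
        discipline="Gastroenterology dept",
        disease="Upper gastrointestinal hemorrhage",
        overview="Black stool for 10 days",
        diagnoses=[
            Diagnosis(label="Chronic gastritis", icd_code="K29.5"),
            Diagnosis(label="Duodenal ulcer", icd_code="K26.9"),
            Diagnosis(
                label="Gastric carcinoma", icd_code="C16.9", is_correct=False
            ),
        ],
        bases=[
            ScoredItem(
                item_id="basis-melena",
                text="Melena for 10 days",
                score_weight=3.0,
                diagnosis_label="Duodenal ulcer",
            ),
            ScoredItem(
                item_id="basis-endoscopy",
                text="Endoscopy shows duodenal bulb ulcer with bleeding",
                score_weight=5.0,
                diagnosis_label="Duodenal ulcer",
            ),
            ScoredItem(
                item_id="basis-epigastric",
                text="Hunger epigastric pain relieved by food",
                score_weight=2.0,
                diagnosis_label="Chronic gastritis",
            ),
            ScoredItem(
                item_id="basis-hb",
                text="Hemoglobin 86 g per L",
                score_weight=2.0,
                diagnosis_label="Duodenal ulcer",
            ),
        ],
        treatments=[
            ScoredItem(
                item_id="tx-ppi",
                text="Proton pump inhibitor and endoscopic hemostasis",
                score_weight=5.0,
            ),
            ScoredItem(
                item_id="tx-nsaid",
                text="Continue NSAID analgesia",
                score_weight=2.0,
                is_correct=False,
            ),
        ],
        recommended_time_s=1500.0,
    )


BUILTIN_TEMPLATES: dict[str, DiseaseTemplate] = {
    t.template_id: t for t in (_hernia_template(), _ugi_template())
}


def get_template(template_id: str) -> DiseaseTemplate:
    try:
        return BUILTIN_TEMPLATES[template_id].model_copy(deep=True)
    except KeyError:
        raise KeyError(
            f"unknown disease template {template_id!r}; "
            f"known: {sorted(BUILTIN_TEMPLATES)}"
        ) from None
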