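"""Seeded synthetic generators for every input the pipeline consumes.

Nothing here is downloaded: lexicons, tagged training corpora, reference
HMMs, standard question libraries, source records and simulated student
traces are all pure functions of their seeds, with ground-truth manifests
returned alongside so every downstream module can be tested end to end.

Segmentation is defined over abstract finite-alphabet symbol sequences;
the generators use lowercase-letter alphabets as one instantiation of
that contract (a real clinical lexicon is another).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel

from .casebuilder import (
    DeidConfig,
    PlayableCase,
    VirtualCase,
    apply_difficulty,
    build_virtual_case,
    deidentify,
    review_action,
)
from .matching import (
    CANDIDATE_CUTOFF,
    MatchOutcome,
    NlpPipeline,
    QuestionLibrary,
    Scene,
    StandardQuestion,
    edit_distance,
)
from .records import DiseaseTemplate, SourceRecord, get_template
from .session import (
    ActionLog,
    SessionScene,
    SessionState,
    ask,
    confirm_candidate,
    finish,
    select_items,
    start_session,
    submit_diagnosis,
    switch_scene,
)
from .textnorm import (
    HmmModel,
    Lexicon,
    STATES,
    TaggedCorpus,
    max_prob_segment,
    tags_for_word,
)

__all__ = [
    "generate_lexicon",
    "generate_tagged_corpus",
    "generate_reference_hmm",
    "sample_from_hmm",
    "generate_question_library",
    "generate_source_record",
    "build_pipeline",
    "CaseFixture",
    "make_case_fixture",
    "StudentTrace",
    "simulate_student",
]

_MAX_WORD_LEN = 4
_LEN_PROBS = (0.15, 0.40, 0.30, 0.15)  # word length 1..4


def _alphabet(size: int) -> str:
    pool = string.ascii_lowercase + string.ascii_uppercase + string.digits
    if size > len(pool):
        raise ValueError(f"alphabet_size must be <= {len(pool)}")
    return pool[:size]


def _draw_word(rng: np.random.Generator, alphabet: str) -> str:
    length = int(rng.choice(_MAX_WORD_LEN, p=_LEN_PROBS)) + 1
    return "".join(rng.choice(list(alphabet), size=length))


def generate_lexicon(
    alphabet_size: int,
    n_words: int,
    zipf_exponent: float = 1.0,
    seed: int = 0,
) -> Lexicon:
    """Distinct words of length 1-4 with Zipf-distributed frequencies.

    The rank-r word gets frequency ``max(1, round(1000 / r**s))`` with
    ``s = zipf_exponent``; ranks follow sampling order, so the draw is
    fully determined by the seed.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    alphabet = _alphabet(alphabet_size)
    capacity = sum(alphabet_size**k for k in range(1, _MAX_WORD_LEN + 1))
    if n_words > capacity:
        raise ValueError(
            f"cannot draw {n_words} distinct words from capacity {capacity}"
        )
    rng = np.random.default_rng(seed)
    words: dict[str, int] = {}
    rank = 1
    while len(words) < n_words:
        w = _draw_word(rng, alphabet)
        if w in words:
            continue
        words[w] = max(1, round(1000.0 / rank**zipf_exponent))
        rank += 1
    return Lexicon(entries=words)


def generate_tagged_corpus(
    lexicon: Lexicon,
    n_sentences: int,
    oov_rate: float = 0.0,
    seed: int = 0,
) -> TaggedCorpus:
    """Sentences concatenated from lexicon words plus injected OOV words.

    Word tokens are drawn proportionally to lexicon frequency; with
    probability ``oov_rate`` a slot instead receives a fresh word outside
    the lexicon. Tags record the true word boundaries (B/M/E or S) and
    ``oov_flags`` records which tokens were injected.
    """
    if not 0.0 <= oov_rate < 1.0:
        raise ValueError("oov_rate must be in [0, 1)")
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(seed)
    vocab = sorted(lexicon.entries)
    freqs = np.array([lexicon.entries[w] for w in vocab], dtype=float)
    probs = freqs / freqs.sum()
    alphabet = "".join(sorted({c for w in vocab for c in w}))
    sentences: list[tuple[str, list[str]]] = []
    flags: list[list[bool]] = []
    for _ in range(n_sentences):
        n_tokens = int(rng.integers(3, 9))
        symbols, tags, sent_flags = "", [], []
        for _ in range(n_tokens):
            if rng.random() < oov_rate:
                while True:
                    w = _draw_word(rng, alphabet)
                    if w not in lexicon:
                        break
                sent_flags.append(True)
            else:
                w = vocab[int(rng.choice(len(vocab), p=probs))]
                sent_flags.append(False)
            symbols += w
            tags.extend(tags_for_word(w))
        sentences.append((symbols, tags))
        flags.append(sent_flags)
    return TaggedCorpus(sentences=sentences, oov_flags=flags)


# ---------------------------------------------------------------------------
# Reference HMMs and sampling
# ---------------------------------------------------------------------------

_LEGAL_NEXT = {"B": ("M", "E"), "M": ("M", "E"), "E": ("B", "S"), "S": ("B", "S")}


def generate_reference_hmm(
    alphabet_size: int = 12,
    seed: int = 0,
    emission_leakage: float = 0.05,
) -> HmmModel:
    """Random BMES HMM whose states are identifiable from the symbols.

    Each state emits mostly from its own quarter of the alphabet (seeded
    Dirichlet weights within the quarter), with ``emission_leakage`` mass
    spread over the remaining symbols. This mirrors real scripts, where
    word-initial and word-final characters have visibly different
    distributions, and makes segmentation from symbols alone well posed —
    the regime in which supervised training on samples from the model can
    recover its parameters and segment held-out text.
    """
    if not 0.0 <= emission_leakage < 1.0:
        raise ValueError("emission_leakage must be in [0, 1)")
    if alphabet_size < len(STATES):
        raise ValueError("alphabet_size must be >= 4 (one symbol per state)")
    rng = np.random.default_rng(seed)
    alphabet = _alphabet(alphabet_size)
    log_initial = dict.fromkeys(STATES, float("-inf"))
    p = rng.dirichlet([2.0, 2.0])
    log_initial["B"], log_initial["S"] = math.log(p[0]), math.log(p[1])
    log_transition: dict[str, dict[str, float]] = {}
    for s in STATES:
        row = dict.fromkeys(STATES, float("-inf"))
        legal = _LEGAL_NEXT[s]
        pr = rng.dirichlet([2.0] * len(legal))
        for t, q in zip(legal, pr):
            row[t] = math.log(q)
        log_transition[s] = row
    preferred = {
        s: [alphabet[j] for j in range(i, alphabet_size, len(STATES))]
        for i, s in enumerate(STATES)
    }
    log_emission: dict[str, dict[str, float]] = {}
    log_unk: dict[str, float] = {}
    for s in STATES:
        own = preferred[s]
        rest = [a for a in alphabet if a not in own]
        probs = dict(zip(own, (1.0 - emission_leakage) * rng.dirichlet([2.0] * len(own))))
        if rest and emission_leakage > 0:
            probs.update(
                zip(rest, emission_leakage * rng.dirichlet([2.0] * len(rest)))
            )
        else:
            probs.update(dict.fromkeys(rest, 0.0))
        log_emission[s] = {
            sym: math.log(max(0.999 * probs[sym], 1e-300)) for sym in alphabet
        }
        log_unk[s] = math.log(0.001)  # reserved unseen-symbol bucket
    return HmmModel(
        log_initial=log_initial,
        log_transition=log_transition,
        log_emission=log_emission,
        log_unk=log_unk,
    )


def sample_from_hmm(
    model: HmmModel,
    n_sentences: int,
    seed: int = 0,
    min_len: int = 5,
    max_len: int = 15,
) -> TaggedCorpus:
    """Sample tagged sentences from an HMM, always ending at a word boundary."""
    rng = np.random.default_rng(seed)
    init_states = [s for s in STATES if model.log_initial[s] > float("-inf")]
    init_p = np.array([math.exp(model.log_initial[s]) for s in init_states])
    init_p /= init_p.sum()
    emis_syms = {s: sorted(model.log_emission[s]) for s in STATES}
    emis_p = {}
    for s in STATES:
        p = np.array([math.exp(model.log_emission[s][x]) for x in emis_syms[s]])
        emis_p[s] = p / p.sum()
    trans_states = {
        s: [t for t in STATES if model.log_transition[s][t] > float("-inf")]
        for s in STATES
    }
    trans_p = {}
    for s in STATES:
        p = np.array(
            [math.exp(model.log_transition[s][t]) for t in trans_states[s]]
        )
        trans_p[s] = p / p.sum()
    sentences = []
    for _ in range(n_sentences):
        target = int(rng.integers(min_len, max_len + 1))
        state = init_states[int(rng.choice(len(init_states), p=init_p))]
        tags = [state]
        while True:
            n = len(tags)
            if n >= target and tags[-1] in ("E", "S"):
                break
            nxt = trans_states[tags[-1]]
            state = nxt[int(rng.choice(len(nxt), p=trans_p[tags[-1]]))]
            tags.append(state)
        symbols = "".join(
            emis_syms[t][int(rng.choice(len(emis_syms[t]), p=emis_p[t]))]
            for t in tags
        )
        sentences.append((symbols, tags))
    return TaggedCorpus(sentences=sentences)


# ---------------------------------------------------------------------------
# Question libraries and source records
# ---------------------------------------------------------------------------

_SCENE_CYCLE = (
    Scene.CONSULTATION,
    Scene.PHYSICAL_EXAM,
    Scene.CONSULTATION,
    Scene.AUXILIARY_EXAM,
    Scene.PHYSICAL_EXAM,
)
_WEIGHT_CHOICES = (1.0, 2.0, 3.0, 5.0)

# Library words are all the same length over a letters-only alphabet: any
# concatenation of them then segments back uniquely under the unigram DP,
# which is what makes generated answer clauses recoverable by the default
# pipeline (asserted below at generation time).
_LIB_WORD_LEN = 3
_LIB_ALPHABET = string.ascii_lowercase[:20]


def generate_question_library(
    n_questions: int = 12,
    seed: int = 0,
    tokens_per_question: tuple[int, int] = (5, 8),
) -> tuple[QuestionLibrary, Lexicon]:
    """Synthetic standard question library plus the lexicon that covers it.

    Canonical token sequences are 5-8 fixed-length words; the returned
    lexicon holds every token with a Zipf-ish frequency, and each
    question's display text is the plain concatenation of its tokens, so
    display text round-trips through segmentation to the canonical tokens.
    """
    if n_questions < 1:
        raise ValueError("n_questions must be >= 1")
    rng = np.random.default_rng(seed)
    vocab_size = max(3 * n_questions, 2 * tokens_per_question[1])
    vocab: list[str] = []
    seen = set()
    while len(vocab) < vocab_size:
        w = "".join(rng.choice(list(_LIB_ALPHABET), size=_LIB_WORD_LEN))
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    entries = {
        w: max(1, round(500.0 / (r + 1))) for r, w in enumerate(vocab)
    }
    lexicon = Lexicon(entries=entries)
    questions = []
    used_tokens: list[list[str]] = []
    for i in range(n_questions):
        # standard questions must be well separated: redraw until this one
        # sits at or beyond the routing cutoff from every existing question,
        # so a clause answering one question can never match another
        for _attempt in range(200):
            k = int(
                rng.integers(tokens_per_question[0], tokens_per_question[1] + 1)
            )
            toks = [
                vocab[int(j)]
                for j in rng.choice(len(vocab), size=k, replace=False)
            ]
            if all(
                edit_distance(toks, prev) >= CANDIDATE_CUTOFF
                for prev in used_tokens
            ):
                break
        else:  # pragma: no cover - capacity made ample by construction
            raise RuntimeError("could not draw a well-separated question")
        used_tokens.append(toks)
        display = "".join(toks)
        seg = max_prob_segment(display, lexicon)
        if seg.tokens != toks:  # pragma: no cover - ruled out by construction
            raise AssertionError("library display text failed to round-trip")
        questions.append(
            StandardQuestion(
                question_id=f"q{i:03d}",
                canonical_tokens=toks,
                display_text=display,
                scene=_SCENE_CYCLE[i % len(_SCENE_CYCLE)],
                answer_text=f"reference-answer-{i:03d}",
                is_correct_item=True,
                score_weight=float(rng.choice(_WEIGHT_CHOICES)),
            )
        )
    return QuestionLibrary(questions=questions), lexicon


def build_pipeline(lexicon: Lexicon, **kwargs) -> NlpPipeline:
    """Default normalisation pipeline over a fixture lexicon."""
    return NlpPipeline(lexicon=lexicon, **kwargs)


_NARRATIVE_SECTIONS = (
    "present_illness",
    "past_history",
    "personal_history",
    "family_history",
    "physical_exam",
)


def generate_source_record(
    disease_template: str,
    library: QuestionLibrary,
    answer_coverage: float = 1.0,
    seed: int = 0,
) -> SourceRecord:
    """Synthetic source record whose narrative answers a known question subset.

    ``ceil(answer_coverage x |library|)`` questions (seeded choice) get
    their display text embedded as a narrative clause; the answer manifest
    records exactly which. PII fields are populated and the patient name
    and record number are additionally embedded inside the narrative, so
    de-identification must scrub free text too.
    """
    if not 0.0 <= answer_coverage <= 1.0:
        raise ValueError("answer_coverage must be in [0, 1]")
    template = get_template(disease_template)
    rng = np.random.default_rng(seed)
    n_cov = math.ceil(answer_coverage * len(library))
    order = [q.question_id for q in library]
    covered = sorted(
        order[int(i)]
        for i in rng.choice(len(order), size=n_cov, replace=False)
    )
    name = "Pt" + "".join(rng.choice(list(string.ascii_lowercase), size=6))
    id_number = "".join(str(int(d)) for d in rng.integers(0, 10, size=8))
    phone = "1" + "".join(str(int(d)) for d in rng.integers(0, 10, size=10))
    admission = f"2023-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
    address = "Ward " + "".join(rng.choice(list(string.ascii_uppercase), size=4))

    sections: dict[str, list[str]] = {s: [] for s in _NARRATIVE_SECTIONS}
    manifest: dict[str, str] = {}
    for j, qid in enumerate(covered):
        clause = library.by_id(qid).display_text
        manifest[qid] = clause
        sections[_NARRATIVE_SECTIONS[j % len(_NARRATIVE_SECTIONS)]].append(clause)
    # PII embedded mid-narrative: the leak scan must catch these too
    sections["present_illness"].append(f"patient {name} admitted {admission}")
    sections["past_history"].append(f"record number {id_number}")
    narrative = {"chief_complaint": template.overview}
    for sec in _NARRATIVE_SECTIONS:
        narrative[sec] = ",".join(sections[sec]) if sections[sec] else "unremarkable"
    structured = {
        "name": name,
        "id_number": id_number,
        "phone": phone,
        "address": address,
        "admission_time": admission,
        "gender": str(rng.choice(["male", "female"])),
        "report_blood": f"Hb {int(rng.integers(70, 160))} g/L",
    }
    return SourceRecord(
        record_id=f"rec-{disease_template}-{seed:04d}",
        structured=structured,
        narrative=narrative,
        true_diagnoses=[d for d in template.diagnoses if d.is_correct],
        pii_manifest={
            k: structured[k]
            for k in ("name", "id_number", "phone", "address", "admission_time")
        },
        answer_manifest=manifest,
        disease_template=disease_template,
    )


# ---------------------------------------------------------------------------
# End-to-end case fixture
# ---------------------------------------------------------------------------


@dataclass
class CaseFixture:
    """Everything needed to play and score one synthetic case."""

    template: DiseaseTemplate
    library: QuestionLibrary
    lexicon: Lexicon
    pipeline: NlpPipeline
    record: SourceRecord
    case: VirtualCase  # released
    playable: PlayableCase


def make_case_fixture(
    template_id: str = "inguinal_hernia",
    seed: int = 0,
    n_questions: int = 12,
    answer_coverage: float = 1.0,
    level: int = 1,
) -> CaseFixture:
    """Generate record -> de-identify -> build -> release -> grade by level."""
    template = get_template(template_id)
    library, lexicon = generate_question_library(n_questions, seed=seed)
    pipeline = build_pipeline(lexicon)
    record = generate_source_record(
        template_id, library, answer_coverage, seed=seed
    )
    clean = deidentify(record, DeidConfig())
    case = build_virtual_case(clean, library, template=template)
    case = review_action(case, "submit_for_review")
    case = review_action(case, "release")
    pool: list[StandardQuestion] = []
    if level == 2:
        other = [t for t in ("inguinal_hernia", "ugi_hemorrhage") if t != template_id]
        pool_lib, _ = generate_question_library(n_questions, seed=seed + 10007)
        pool = [
            q.model_copy(update={"question_id": f"{other[0]}-{q.question_id}"})
            for q in pool_lib
        ]
    playable = apply_difficulty(case, level, seed=seed, distractor_pool=pool)
    return CaseFixture(
        template=template,
        library=library,
        lexicon=lexicon,
        pipeline=pipeline,
        record=record,
        case=case,
        playable=playable,
    )


# ---------------------------------------------------------------------------
# Simulated students
# ---------------------------------------------------------------------------


class StudentTrace(BaseModel):
    """A reproducible simulated learning session."""

    competence: float
    seed: int
    actions: ActionLog


# probability scale for selecting not-indicated items; zero at competence 1
_WRONG_ITEM_SCALE = 0.3


def simulate_student(
    fixture: CaseFixture,
    competence: float,
    seed: int = 0,
    time_noise_sd: float = 0.1,
) -> tuple[StudentTrace, SessionState]:
    """Simulate one student session on a playable case.

    Each correct item is selected independently with probability equal to
    ``competence``; each not-indicated item with probability
    ``0.3 x (1 - competence)``. Completion time is the recommended time
    scaled by ``(2 - competence)`` with seeded lognormal noise
    (``time_noise_sd=0`` gives the exact scaled time).
    """
    if not 0.0 <= competence <= 1.0:
        raise ValueError("competence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    playable = fixture.playable
    wrong_p = _WRONG_ITEM_SCALE * (1.0 - competence)
    session = start_session(
        playable, f"student-{seed}", fixture.pipeline, session_id=f"sim-{seed}"
    )
    for scene in (
        SessionScene.CONSULTATION,
        SessionScene.PHYSICAL_EXAM,
        SessionScene.AUXILIARY_EXAM,
    ):
        switch_scene(session, scene)
        for q in playable.questions_for_scene(
            {"consultation": Scene.CONSULTATION,
             "physical_exam": Scene.PHYSICAL_EXAM,
             "auxiliary_exam": Scene.AUXILIARY_EXAM}[scene.value]
        ):
            p = competence if q.is_correct_item else wrong_p
            if rng.random() < p:
                result = ask(session, q.display_text)
                if result.outcome is MatchOutcome.CANDIDATES:
                    confirm_candidate(session, result.candidates[0][0].question_id)
    switch_scene(session, SessionScene.DIAGNOSIS)
    for d in playable.base.diagnoses:
        p = competence if d.is_correct else wrong_p
        if rng.random() < p:
            submit_diagnosis(session, d.label)
    base_ids = [
        b.item_id
        for b in playable.base.diagnosis_bases
        if rng.random() < (competence if b.is_correct else wrong_p)
    ]
    if base_ids:
        select_items(session, "bases", base_ids)
    switch_scene(session, SessionScene.TREATMENT)
    tx_ids = [
        t.item_id
        for t in playable.base.treatments
        if rng.random() < (competence if t.is_correct else wrong_p)
    ]
    if tx_ids:
        select_items(session, "treatments", tx_ids)
    t_rec = playable.base.recommended_completion_time
    noise = math.exp(rng.normal(0.0, time_noise_sd)) if time_noise_sd > 0 else 1.0
    t_act = t_rec * (2.0 - competence) * noise
    end_at = max(session._clock + 1.0, session.start_time + t_act)
    log = finish(session, at=end_at)
    trace = StudentTrace(competence=competence, seed=seed, actions=log)
    return trace, session
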