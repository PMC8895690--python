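"""Mapping free-text student questions onto a standard question library.

Student questions are segmented, each token is synonym-converted to its
cosine-nearest standard term in a word-vector model, and the normalised
token sequence is routed against the library by token-level Levenshtein
distance: distance 0 returns the question's answer directly; small
distances (below the candidate cutoff) produce a ranked candidate set the
student must reconfirm; anything farther is a process deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .textnorm import (
    DEFAULT_RULES,
    HmmModel,
    Lexicon,
    NegationAnnotation,
    RulePattern,
    Trie,
    annotate_negation,
    build_trie,
    segment,
)

__all__ = [
    "VectorModel",
    "train_vectors",
    "nearest_standard_term",
    "StandardQuestion",
    "QuestionLibrary",
    "Scene",
    "MatchOutcome",
    "MatchResult",
    "NlpPipeline",
    "edit_distance",
    "match_question",
    "DEVIATION_MESSAGE",
    "CANDIDATE_CUTOFF",
    "SIMILARITY_THRESHOLD",
]

# Routing thresholds: distance 0 is an exact match; 0 < d < CANDIDATE_CUTOFF
# yields a ranked candidate set; d >= CANDIDATE_CUTOFF is a deviation.
CANDIDATE_CUTOFF = 5
DEVIATION_MESSAGE = "You have deviated from the correct process"
# Minimum cosine similarity for replacing a token by a standard term.
SIMILARITY_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# Word vectors: count-based PPMI + truncated SVD embedding
# ---------------------------------------------------------------------------


@dataclass
class VectorModel:
    """Per-word embedding with a flagged subset of canonical standard terms.

    Vectors come from a positive pointwise-mutual-information co-occurrence
    matrix factorised by SVD, so words sharing contexts end up close in
    cosine; the matching contract only relies on that cosine-nearest
    behaviour.
    """

    vocabulary: list[str]
    vectors: np.ndarray  # (n_words, dim)
    standard_terms: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        for t in self.standard_terms:
            if t not in self._index:
                raise ValueError(f"standard term {t!r} not in vocabulary")
            if not np.any(self.vectors[self._index[t]]):
                raise ValueError(f"standard term {t!r} has a zero vector")

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "vectors": {
                    w: [float(x) for x in self.vectors[i]]
                    for w, i in self._index.items()
                },
                "standard_terms": self.standard_terms,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "VectorModel":
        d = json.loads(text)
        vocab = list(d["vectors"])
        vectors = np.array([d["vectors"][w] for w in vocab], dtype=float)
        return cls(
            vocabulary=vocab, vectors=vectors, standard_terms=d["standard_terms"]
        )


def train_vectors(
    corpus: Sequence[Sequence[str]],
    dim: int = 16,
    window: int = 2,
    seed: int = 0,
    standard_terms: Iterable[str] = (),
) -> VectorModel:
    """Train a PPMI+SVD word embedding on tokenised sentences.

    Deterministic for a fixed seed (the SVD sign ambiguity is resolved by
    forcing the largest-magnitude loading of each component positive).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not corpus:
        raise ValueError("corpus must be non-empty")
    vocab = sorted({w for sent in corpus for w in sent})
    if len(vocab) < 2:
        raise ValueError("vocabulary must contain at least 2 words")
    idx = {w: i for i, w in enumerate(vocab)}
    n = len(vocab)
    counts = np.zeros((n, n), dtype=float)
    for sent in corpus:
        ids = [idx[w] for w in sent]
        for i, wi in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    counts[wi, ids[j]] += 1.0

    total = counts.sum()
    if total == 0:
        raise ValueError("corpus has no co-occurrences within the window")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row @ col))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    k = min(dim, n)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    vecs = u[:, :k] * np.sqrt(s[:k])
    # deterministic sign convention per component
    for c in range(vecs.shape[1]):
        pivot = np.argmax(np.abs(vecs[:, c]))
        if vecs[pivot, c] < 0:
            vecs[:, c] = -vecs[:, c]
    if k < dim:
        vecs = np.hstack([vecs, np.zeros((n, dim - k))])
    # tiny seeded jitter breaks exact-zero vectors deterministically
    rng = np.random.default_rng(seed)
    jitter = rng.normal(scale=1e-9, size=vecs.shape)
    vecs = vecs + jitter
    return VectorModel(
        vocabulary=vocab,
        vectors=vecs,
        standard_terms=[t for t in standard_terms if t in idx],
    )


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def nearest_standard_term(
    word: str,
    model: VectorModel,
    threshold: float = SIMILARITY_THRESHOLD,
) -> tuple[str, float]:
    """Cosine-nearest standard term for a word, with threshold gating.

    A word that is itself a standard term maps to itself with similarity 1;
    a word outside the vocabulary passes through unchanged; otherwise the
    argmax-cosine standard term replaces the word only when the similarity
    reaches ``threshold``.
    """
    if not model.standard_terms:
        raise ValueError("model has no standard terms")
    if word in model.standard_terms:
        return word, 1.0
    if word not in model:
        return word, 0.0
    v = model.vector(word)
    best_term, best_sim = None, -math.inf
    for term in model.standard_terms:
        sim = cosine(v, model.vector(term))
        if sim > best_sim or (sim == best_sim and best_term is not None and term < best_term):
            best_term, best_sim = term, sim
    assert best_term is not None
    if best_sim >= threshold:
        return best_term, best_sim
    return word, best_sim


# ---------------------------------------------------------------------------
# Standard question library
# ---------------------------------------------------------------------------


class Scene(str, Enum):
    CONSULTATION = "consultation"
    PHYSICAL_EXAM = "physical_exam"
    AUXILIARY_EXAM = "auxiliary_exam"


class StandardQuestion(BaseModel):
    """One canonical question: the matching target and scoring item."""

    question_id: str
    canonical_tokens: list[str] = Field(min_length=1)
    display_text: str
    scene: Scene
    answer_text: str = ""
    is_correct_item: bool = True
    score_weight: float = Field(default=1.0, ge=0.0)

    @field_validator("canonical_tokens")
    @classmethod
    def _non_empty_tokens(cls, v: list[str]) -> list[str]:
        if any(not t for t in v):
            raise ValueError("canonical tokens must be non-empty")
        return v


class QuestionLibrary(BaseModel):
    """Ordered collection of standard questions with id lookup."""

    questions: list[StandardQuestion]

    def __iter__(self):
        return iter(self.questions)

    def __len__(self) -> int:
        return len(self.questions)

    def by_id(self, question_id: str) -> StandardQuestion:
        for q in self.questions:
            if q.question_id == question_id:
                return q
        raise KeyError(question_id)

    def for_scene(self, scene: Scene) -> list[StandardQuestion]:
        return [q for q in self.questions if q.scene == scene]

    def to_json(self) -> str:
        return json.dumps(
            [q.model_dump(mode="json") for q in self.questions],
            ensure_ascii=False,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "QuestionLibrary":
        return cls(questions=[StandardQuestion(**d) for d in json.loads(text)])


# ---------------------------------------------------------------------------
# Edit distance and routing
# ---------------------------------------------------------------------------


def edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Levenshtein distance over token sequences (unit costs).

    Distance is over whole tokens, not symbols: synonym conversion operates
    on tokens, and symbol-level distance would undo it.
    """
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, 1):
        cur = [i]
        for j, tb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ta != tb),
                )
            )
        prev = cur
    return prev[-1]


class MatchOutcome(str, Enum):
    EXACT = "EXACT"
    CANDIDATES = "CANDIDATES"
    DEVIATED = "DEVIATED"


@dataclass
class MatchResult:
    """Routing result for one student question."""

    outcome: MatchOutcome
    matched: StandardQuestion | None = None
    candidates: list[tuple[StandardQuestion, int]] = field(default_factory=list)
    message: str | None = None
    normalized_tokens: list[str] = field(default_factory=list)
    negation: NegationAnnotation | None = None


@dataclass
class NlpPipeline:
    """Bundle of everything needed to normalise student text.

    The vector model and HMM are optional: without vectors tokens pass
    through synonym conversion unchanged; without an HMM, out-of-vocabulary
    symbols stay single-symbol tokens.
    """

    lexicon: Lexicon
    hmm: HmmModel | None = None
    vectors: VectorModel | None = None
    qualifiers: tuple[str, ...] = ()
    rules: Sequence[RulePattern] = ()
    similarity_threshold: float = SIMILARITY_THRESHOLD
    candidate_cutoff: int = CANDIDATE_CUTOFF
    _trie: Trie | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._trie = build_trie(self.lexicon)

    def normalize(
        self, text: str
    ) -> tuple[list[str], NegationAnnotation]:
        """Segment -> synonym-map each token -> annotate negation."""
        if not text:
            raise ValueError("text must be non-empty")
        tokens: list[str] = []
        for chunk in text.split():
            seg = segment(
                chunk, self.lexicon, self.hmm, self.rules, trie=self._trie
            )
            tokens.extend(seg.tokens)
        if self.vectors is not None and self.vectors.standard_terms:
            tokens = [
                nearest_standard_term(
                    t, self.vectors, self.similarity_threshold
                )[0]
                for t in tokens
            ]
        ann = annotate_negation(tokens, self.qualifiers)
        return tokens, ann


def normalize_question(text: str, pipeline: NlpPipeline) -> list[str]:
    """Canonical token sequence for free student text."""
    tokens, _ = pipeline.normalize(text)
    return tokens


def match_question(
    text: str,
    library: QuestionLibrary,
    pipeline: NlpPipeline,
) -> MatchResult:
    """Route one student question against the standard library.

    Computes the minimum token edit distance over the library after
    normalisation: 0 is an exact hit whose answer is returned directly;
    positive distances below the candidate cutoff return every question
    under the cutoff sorted by (distance, question_id) for the student to
    reconfirm; otherwise the verbatim deviation message is returned.
    """
    if len(library) == 0:
        raise ValueError("question library must be non-empty")
    tokens, ann = pipeline.normalize(text)
    # content tokens only: clause delimiters carry no matching information
    content = [
        t
        for t, pol in zip(tokens, ann.polarity)
        if pol != "delimiter"
    ]
    scored = sorted(
        (
            (edit_distance(content, q.canonical_tokens), q.question_id, q)
            for q in library
        ),
    )
    d_star = scored[0][0]
    if d_star == 0:
        return MatchResult(
            outcome=MatchOutcome.EXACT,
            matched=scored[0][2],
            candidates=[(scored[0][2], 0)],
            normalized_tokens=tokens,
            negation=ann,
        )
    if d_star < pipeline.candidate_cutoff:
        cands = [
            (q, d) for d, _qid, q in scored if d < pipeline.candidate_cutoff
        ]
        return MatchResult(
            outcome=MatchOutcome.CANDIDATES,
            candidates=cands,
            normalized_tokens=tokens,
            negation=ann,
        )
    return MatchResult(
        outcome=MatchOutcome.DEVIATED,
        message=DEVIATION_MESSAGE,
        normalized_tokens=tokens,
        negation=ann,
    )
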