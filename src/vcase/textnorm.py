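"""Word segmentation and text normalisation for unsegmented symbol text.

The pipeline mirrors the classic statistical segmentation stack used for
Chinese clinical text, but is defined over arbitrary finite-alphabet symbol
sequences (a string is a sequence of single-character symbols; real scripts
are one instantiation):

1. anchored rule patterns freeze numeric/template spans (dates, values with
   units) as single tokens;
2. a dictionary trie drives word-graph scanning: a directed acyclic graph
   whose forward edges are all lexicon-admissible word formations;
3. dynamic programming selects the maximum-probability path under a unigram
   word-frequency model (right-to-left over the DAG);
4. maximal runs of leftover single-symbol out-of-vocabulary (OOV) tokens are
   re-decoded by a character-level BMES hidden Markov model with Viterbi,
   so unknown colloquial words are formed from symbol tag sequences;
5. negation qualifiers are annotated over the token stream with a
   clause-bounded forward scope.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Lexicon",
    "Trie",
    "WordGraph",
    "Segmentation",
    "RulePattern",
    "HmmModel",
    "NegationAnnotation",
    "build_trie",
    "build_word_graph",
    "max_prob_segment",
    "apply_rule_patterns",
    "train_hmm",
    "viterbi_decode",
    "segment",
    "annotate_negation",
    "boundary_prf",
    "DEFAULT_RULES",
    "STATES",
]

# BMES state order is fixed: it is also the Viterbi tie-break order.
STATES: tuple[str, ...] = ("B", "M", "E", "S")
_S = {s: i for i, s in enumerate(STATES)}

# Legal BMES automaton: words are B M* E or S.
_LEGAL_NEXT = {"B": ("M", "E"), "M": ("M", "E"), "E": ("B", "S"), "S": ("B", "S")}
_LEGAL_START = ("B", "S")
_LEGAL_END = ("E", "S")

NEG_INF = float("-inf")

# Default probability floor factor for single-symbol OOV fallback tokens:
# P(oov symbol) = floor_factor / total_count, so any dictionary word with
# frequency >= 1 is strictly preferred over an OOV symbol.
DEFAULT_OOV_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lexicon:
    """Word -> frequency table over a finite symbol alphabet.

    ``total_count`` is the sum of all frequencies; unigram word probability
    is ``freq(word) / total_count``.
    """

    entries: Mapping[str, int]
    total_count: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon must contain at least one word")
        for w, f in self.entries.items():
            if not w:
                raise ValueError("lexicon words must be non-empty")
            if f <= 0:
                raise ValueError(f"frequency of {w!r} must be positive, got {f}")
        object.__setattr__(self, "total_count", sum(self.entries.values()))

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def log_prob(self, word: str) -> float:
        return math.log(self.entries[word]) - math.log(self.total_count)

    def to_text(self) -> str:
        """Two-column ``word<TAB>count`` serialisation."""
        return "".join(f"{w}\t{f}\n" for w, f in sorted(self.entries.items()))

    @classmethod
    def from_text(cls, text: str) -> "Lexicon":
        entries: dict[str, int] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            word, count = line.rstrip("\n").split("\t")
            entries[word] = int(count)
        return cls(entries)


# ---------------------------------------------------------------------------
# Trie and word graph
# ---------------------------------------------------------------------------


class Trie:
    """Prefix tree over lexicon words; leaves carry word frequency."""

    __slots__ = ("_children", "_freq")

    def __init__(self) -> None:
        self._children: dict[str, Trie] = {}
        self._freq: int | None = None

    def insert(self, word: str, freq: int) -> None:
        node = self
        for sym in word:
            node = node._children.setdefault(sym, Trie())
        node._freq = freq

    def member(self, word: str) -> bool:
        node = self._walk(word)
        return node is not None and node._freq is not None

    def prefix(self, text: str) -> bool:
        return self._walk(text) is not None

    def freq(self, word: str) -> int | None:
        node = self._walk(word)
        return None if node is None else node._freq

    def _walk(self, text: str) -> "Trie | None":
        node = self
        for sym in text:
            node = node._children.get(sym)
            if node is None:
                return None
        return node

    def matches_from(self, sentence: str, start: int) -> list[int]:
        """End indices j > start such that sentence[start:j] is a word."""
        out: list[int] = []
        node = self
        for j in range(start, len(sentence)):
            node = node._children.get(sentence[j])
            if node is None:
                break
            if node._freq is not None:
                out.append(j + 1)
        return out


def build_trie(lexicon: Lexicon) -> Trie:
    """Index all lexicon words for word-graph scanning."""
    trie = Trie()
    for word, freq in lexicon.entries.items():
        trie.insert(word, freq)
    return trie


@dataclass
class WordGraph:
    """DAG of all admissible word formations over a sentence.

    ``edges[i]`` holds all end positions j such that ``sentence[i:j]`` is a
    lexicon word; the single-symbol edge ``j = i + 1`` is always admissible
    so the graph always admits at least one full path.
    """

    sentence: str
    edges: list[list[int]]

    def path_count(self) -> int:
        """Number of distinct full segmentations (root-to-end paths)."""
        n = len(self.sentence)
        counts = [0] * (n + 1)
        counts[n] = 1
        for i in range(n - 1, -1, -1):
            counts[i] = sum(counts[j] for j in self.edges[i])
        return counts[0]


def build_word_graph(sentence: str, trie: Trie) -> WordGraph:
    if not sentence:
        raise ValueError("sentence must be non-empty")
    edges: list[list[int]] = []
    for i in range(len(sentence)):
        ends = trie.matches_from(sentence, i)
        if i + 1 not in ends:
            ends = [i + 1] + ends
        edges.append(sorted(ends))
    return WordGraph(sentence=sentence, edges=edges)


# ---------------------------------------------------------------------------
# Maximum-probability segmentation (DP over the DAG)
# ---------------------------------------------------------------------------


@dataclass
class Segmentation:
    """Tokenisation of a sentence: tokens, half-open spans and per-token source.

    Invariant: spans tile the sentence exactly, so the concatenation of
    ``tokens`` reproduces it.
    """

    tokens: list[str]
    spans: list[tuple[int, int]]
    source: list[str]  # per token: DICT | RULE | OOV

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def score(self, lexicon: Lexicon, oov_floor: float = DEFAULT_OOV_FLOOR) -> float:
        return sum(
            segment_log_prob(tok, lexicon, oov_floor) for tok in self.tokens
        )


def segment_log_prob(
    word: str, lexicon: Lexicon, oov_floor: float = DEFAULT_OOV_FLOOR
) -> float:
    """Unigram log-probability of one token; OOV symbols get the floor."""
    if word in lexicon:
        return lexicon.log_prob(word)
    return math.log(oov_floor) - math.log(lexicon.total_count)


def max_prob_segment(
    sentence: str,
    lexicon: Lexicon,
    oov_floor: float = DEFAULT_OOV_FLOOR,
    trie: Trie | None = None,
) -> Segmentation:
    """Maximum-probability path through the word graph.

    Dynamic programming runs right-to-left: ``best[i]`` is the best score of
    segmenting ``sentence[i:]``. Ties are broken by preferring fewer tokens,
    then the lexicographically earliest boundary tuple, so the result is a
    deterministic function of (sentence, lexicon).
    """
    if not sentence:
        raise ValueError("sentence must be non-empty")
    if trie is None:
        trie = build_trie(lexicon)
    graph = build_word_graph(sentence, trie)
    n = len(sentence)
    # per position: (score, n_tokens, boundary tuple from this position)
    best: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, ())] * (n + 1)
    for i in range(n - 1, -1, -1):
        cand: tuple[float, int, tuple[int, ...]] | None = None
        for j in graph.edges[i]:
            lp = segment_log_prob(sentence[i:j], lexicon, oov_floor)
            sc, nt, bounds = best[j]
            c = (lp + sc, nt + 1, (j,) + bounds)
            if cand is None or _better(c, cand):
                cand = c
        assert cand is not None
        best[i] = cand
    bounds = (0,) + best[0][2]
    tokens, spans, source = [], [], []
    for a, b in zip(bounds, bounds[1:]):
        word = sentence[a:b]
        tokens.append(word)
        spans.append((a, b))
        source.append("DICT" if word in lexicon else "OOV")
    return Segmentation(tokens=tokens, spans=spans, source=source)


def _better(
    a: tuple[float, int, tuple[int, ...]], b: tuple[float, int, tuple[int, ...]]
) -> bool:
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] < b[1]
    return a[2] < b[2]


# ---------------------------------------------------------------------------
# Rule model for numeric / template spans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RulePattern:
    rule_id: str
    pattern: re.Pattern[str]


def make_rules(named: Mapping[str, str]) -> list[RulePattern]:
    return [RulePattern(rid, re.compile(pat)) for rid, pat in named.items()]


# Numeric and template spans common in medical narratives; matched spans are
# frozen as single tokens before word-graph construction.
DEFAULT_RULES: list[RulePattern] = make_rules(
    {
        "duration": r"\d+\s*(?:days?|weeks?|months?|years?|hours?|天|日|周|月|年)",
        "value_range": r"\d+(?:\.\d+)?\s*[-~–]\s*\d+(?:\.\d+)?",
        "measurement": r"\d+(?:\.\d+)?\s*(?:mg|g|kg|ml|l|mmHg|°C|℃|cm|mm|%|次)",
        "date": r"\d{4}[-/.]\d{1,2}[-/.]\d{1,2}",
        "number": r"\d+(?:\.\d+)?",
    }
)


def apply_rule_patterns(
    sentence: str, rules: Sequence[RulePattern]
) -> list[tuple[tuple[int, int], str, str]]:
    """Non-overlapping leftmost-longest rule matches as ((start, end), token, rule_id).

    Overlaps are resolved deterministically: earlier start wins, then longer
    match, then rule order as given.
    """
    hits: list[tuple[int, int, int, str]] = []
    for order, rule in enumerate(rules):
        for m in rule.pattern.finditer(sentence):
            if m.start() < m.end():
                hits.append((m.start(), -(m.end() - m.start()), order, rule.rule_id))
    hits.sort()
    out: list[tuple[tuple[int, int], str, str]] = []
    taken_until = -1
    for start, neglen, _order, rid in hits:
        end = start - neglen
        if start > taken_until:
            out.append(((start, end), sentence[start:end], rid))
            taken_until = end - 1
    return out


# ---------------------------------------------------------------------------
# BMES character HMM
# ---------------------------------------------------------------------------


@dataclass
class HmmModel:
    """Character-tagging HMM over BMES states, parameters in log space.

    ``log_emission[state]`` maps observed symbols to log-probabilities;
    ``log_unk[state]`` is the smoothing mass reserved for unseen symbols, so
    each emission distribution (observed symbols + one unseen bucket) sums
    to one. Illegal BMES transitions carry -inf.
    """

    log_initial: dict[str, float]
    log_transition: dict[str, dict[str, float]]
    log_emission: dict[str, dict[str, float]]
    log_unk: dict[str, float]

    def emission(self, state: str, symbol: str) -> float:
        return self.log_emission[state].get(symbol, self.log_unk[state])

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_initial": self.log_initial,
                "log_transition": self.log_transition,
                "log_emission": self.log_emission,
                "log_unk": self.log_unk,
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        d = json.loads(text)
        return cls(
            log_initial=d["log_initial"],
            log_transition={s: dict(v) for s, v in d["log_transition"].items()},
            log_emission={s: dict(v) for s, v in d["log_emission"].items()},
            log_unk=d["log_unk"],
        )


@dataclass
class TaggedCorpus:
    """Symbol/tag sentence pairs for supervised BMES training.

    ``oov_flags`` (optional, parallel to sentences) marks which word tokens
    were out-of-vocabulary at generation time; it is generator ground truth,
    not training input.
    """

    sentences: list[tuple[str, list[str]]]
    tagset: tuple[str, ...] = STATES
    oov_flags: list[list[bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for symbols, tags in self.sentences:
            if len(symbols) != len(tags):
                raise ValueError("symbol/tag length mismatch")
            _check_bmes(tags)

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps({"symbols": list(sy), "tags": tg}, ensure_ascii=False) + "\n"
            for sy, tg in self.sentences
        )

    @classmethod
    def from_jsonl(cls, text: str) -> "TaggedCorpus":
        sentences = []
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            sentences.append(("".join(d["symbols"]), list(d["tags"])))
        return cls(sentences=sentences)


def _check_bmes(tags: Sequence[str]) -> None:
    if not tags:
        raise ValueError("empty tag sequence")
    if tags[0] not in _LEGAL_START:
        raise ValueError(f"tag sequence starts with {tags[0]}")
    for a, b in zip(tags, tags[1:]):
        if b not in _LEGAL_NEXT[a]:
            raise ValueError(f"illegal transition {a}->{b}")
    if tags[-1] not in _LEGAL_END:
        raise ValueError(f"tag sequence ends with {tags[-1]}")


def tags_for_word(word: str) -> list[str]:
    """Gold BMES tags for one word: S, or B M* E."""
    if len(word) == 1:
        return ["S"]
    return ["B"] + ["M"] * (len(word) - 2) + ["E"]


def words_from_tags(span: str, tags: Sequence[str]) -> list[str]:
    """Split a symbol span into words at B/S starts of a BMES sequence."""
    words: list[str] = []
    start = 0
    for i, t in enumerate(tags):
        if i > 0 and t in ("B", "S"):
            words.append(span[start:i])
            start = i
    words.append(span[start:])
    return words


def train_hmm(corpus: TaggedCorpus, smoothing: float = 1.0) -> HmmModel:
    """Maximum-likelihood BMES HMM with additive smoothing.

    Transition probabilities are smoothed only over the legal successor set
    of each state; illegal transitions stay at -inf. Emissions are smoothed
    over the observed symbol alphabet plus one unseen bucket per state.
    """
    if not corpus.sentences:
        raise ValueError("corpus must be non-empty")
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    init = dict.fromkeys(STATES, 0.0)
    trans = {s: dict.fromkeys(STATES, 0.0) for s in STATES}
    emit: dict[str, dict[str, float]] = {s: {} for s in STATES}
    alphabet: set[str] = set()
    for symbols, tags in corpus.sentences:
        init[tags[0]] += 1
        for a, b in zip(tags, tags[1:]):
            trans[a][b] += 1
        for sym, t in zip(symbols, tags):
            emit[t][sym] = emit[t].get(sym, 0.0) + 1
            alphabet.add(sym)

    log_initial = _smooth_log(init, _LEGAL_START, smoothing)
    log_transition = {
        s: _smooth_log(trans[s], _LEGAL_NEXT[s], smoothing) for s in STATES
    }
    log_emission: dict[str, dict[str, float]] = {}
    log_unk: dict[str, float] = {}
    v = len(alphabet) + 1  # +1 unseen bucket
    for s in STATES:
        total = sum(emit[s].values()) + smoothing * v
        log_emission[s] = {
            sym: math.log(emit[s].get(sym, 0.0) + smoothing) - math.log(total)
            for sym in sorted(alphabet)
        }
        log_unk[s] = math.log(smoothing) - math.log(total)
    return HmmModel(
        log_initial=log_initial,
        log_transition=log_transition,
        log_emission=log_emission,
        log_unk=log_unk,
    )


def _smooth_log(
    counts: Mapping[str, float], legal: Sequence[str], smoothing: float
) -> dict[str, float]:
    total = sum(counts[s] for s in legal) + smoothing * len(legal)
    out = dict.fromkeys(STATES, NEG_INF)
    for s in legal:
        out[s] = math.log(counts[s] + smoothing) - math.log(total)
    return out


def viterbi_decode(span: str, model: HmmModel) -> list[str]:
    """Most-probable legal BMES tag sequence for a symbol span.

    The terminal state is constrained to E or S so the decoded sequence
    always parses into complete words. Ties are broken by the fixed state
    order B < M < E < S at every backpointer.
    """
    if not span:
        raise ValueError("span must be non-empty")
    n = len(span)
    score = [[NEG_INF] * 4 for _ in range(n)]
    back = [[0] * 4 for _ in range(n)]
    for si, s in enumerate(STATES):
        score[0][si] = model.log_initial[s] + model.emission(s, span[0])
    for i in range(1, n):
        for si, s in enumerate(STATES):
            em = model.emission(s, span[i])
            bi, bsc = 0, NEG_INF
            for pi, p in enumerate(STATES):
                sc = score[i - 1][pi] + model.log_transition[p][s]
                if sc > bsc:  # strict: first (lowest state index) wins ties
                    bi, bsc = pi, sc
            score[i][si] = bsc + em
            back[i][si] = bi
    end_states = [_S[s] for s in _LEGAL_END]
    last = max(end_states, key=lambda si: (score[n - 1][si], -si))
    # prefer lower state index on exact tie
    for si in end_states:
        if score[n - 1][si] == score[n - 1][last] and si < last:
            last = si
    tags = [last]
    for i in range(n - 1, 0, -1):
        tags.append(back[i][tags[-1]])
        # walk backwards through backpointers
    tags.reverse()
    return [STATES[i] for i in tags]


def sequence_log_prob(span: str, tags: Sequence[str], model: HmmModel) -> float:
    """Joint log-probability of (tags, span) under the model."""
    lp = model.log_initial[tags[0]] + model.emission(tags[0], span[0])
    for i in range(1, len(span)):
        lp += model.log_transition[tags[i - 1]][tags[i]]
        lp += model.emission(tags[i], span[i])
    return lp


# ---------------------------------------------------------------------------
# Full segmentation pipeline
# ---------------------------------------------------------------------------


def segment(
    sentence: str,
    lexicon: Lexicon,
    model: HmmModel | None = None,
    rules: Sequence[RulePattern] = (),
    oov_floor: float = DEFAULT_OOV_FLOOR,
    trie: Trie | None = None,
) -> Segmentation:
    """Rule freezing -> DP over the word graph -> HMM re-decode of OOV runs.

    Rule-matched spans are frozen as single tokens first; the remaining gaps
    are segmented by the maximum-probability DP; maximal runs of consecutive
    single-symbol OOV fallback tokens are then re-decoded by Viterbi and
    merged into OOV words. The output spans always tile the input.
    """
    if not sentence:
        raise ValueError("sentence must be non-empty")
    if trie is None:
        trie = build_trie(lexicon)
    frozen = apply_rule_patterns(sentence, rules) if rules else []
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    source: list[str] = []

    def emit_gap(a: int, b: int) -> None:
        if a >= b:
            return
        seg = max_prob_segment(sentence[a:b], lexicon, oov_floor, trie=trie)
        for tok, (s0, s1), src in zip(seg.tokens, seg.spans, seg.source):
            tokens.append(tok)
            spans.append((a + s0, a + s1))
            source.append(src)

    pos = 0
    for (a, b), tok, _rid in frozen:
        emit_gap(pos, a)
        tokens.append(tok)
        spans.append((a, b))
        source.append("RULE")
        pos = b
    emit_gap(pos, len(sentence))

    if model is not None:
        tokens, spans, source = _merge_oov_runs(
            sentence, tokens, spans, source, model
        )
    return Segmentation(tokens=tokens, spans=spans, source=source)


def _merge_oov_runs(
    sentence: str,
    tokens: list[str],
    spans: list[tuple[int, int]],
    source: list[str],
    model: HmmModel,
) -> tuple[list[str], list[tuple[int, int]], list[str]]:
    out_t: list[str] = []
    out_sp: list[tuple[int, int]] = []
    out_src: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        is_run = (
            source[i] == "OOV"
            and len(tokens[i]) == 1
        )
        if not is_run:
            out_t.append(tokens[i])
            out_sp.append(spans[i])
            out_src.append(source[i])
            i += 1
            continue
        j = i
        while (
            j < n
            and source[j] == "OOV"
            and len(tokens[j]) == 1
            and spans[j][0] == (spans[j - 1][1] if j > i else spans[i][0])
        ):
            j += 1
        a, b = spans[i][0], spans[j - 1][1]
        run = sentence[a:b]
        if len(run) > 1:
            tags = viterbi_decode(run, model)
            pos = a
            for word in words_from_tags(run, tags):
                out_t.append(word)
                out_sp.append((pos, pos + len(word)))
                out_src.append("OOV")
                pos += len(word)
        else:
            out_t.append(run)
            out_sp.append((a, b))
            out_src.append("OOV")
        i = j
    return out_t, out_sp, out_src


def boundary_prf(
    gold: Iterable[Sequence[str]], pred: Iterable[Sequence[str]]
) -> tuple[float, float, float]:
    """Word-boundary precision/recall/F1 between two tokenisations.

    Each tokenisation is scored as the set of (start, end) word spans; this
    is the standard segmentation evaluation and supports model comparisons.
    """
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        gs = set(_spans_of(g))
        ps = set(_spans_of(p))
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def _spans_of(tokens: Sequence[str]) -> list[tuple[int, int]]:
    spans = []
    pos = 0
    for t in tokens:
        spans.append((pos, pos + len(t)))
        pos += len(t)
    return spans


# ---------------------------------------------------------------------------
# Negation annotation
# ---------------------------------------------------------------------------

# Clause delimiters bound the forward scope of a negation qualifier.
DEFAULT_CLAUSE_DELIMITERS = frozenset({",", ".", ";", "?", "!", "，", "。", "；", "？", "！"})


@dataclass
class NegationAnnotation:
    """Qualifier hits and per-token polarity over a token stream."""

    qualifier_hits: list[tuple[str, list[int]]]
    polarity: list[str]  # per token: affirmed | negated | qualifier | delimiter


def annotate_negation(
    tokens: Sequence[str],
    qualifiers: Iterable[str],
    clause_delimiters: frozenset[str] = DEFAULT_CLAUSE_DELIMITERS,
) -> NegationAnnotation:
    """Clause-bounded forward negation with flip-on-repeat.

    Tokens after a qualifier, up to the end of the clause, flip polarity;
    a second qualifier in the same clause flips it back (double negation).
    """
    qset = set(qualifiers)
    polarity: list[str] = []
    hits: list[tuple[str, list[int]]] = []
    negated = False
    open_scopes: list[list[int]] = []
    for i, tok in enumerate(tokens):
        if tok in clause_delimiters:
            polarity.append("delimiter")
            negated = False
            open_scopes = []
        elif tok in qset:
            polarity.append("qualifier")
            negated = not negated
            scope: list[int] = []
            hits.append((tok, scope))
            open_scopes.append(scope)
        else:
            polarity.append("negated" if negated else "affirmed")
            for scope in open_scopes:
                scope.append(i)
    return NegationAnnotation(qualifier_hits=hits, polarity=polarity)
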