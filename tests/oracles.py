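"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the implementation: segmentations
and tag sequences are enumerated exhaustively, and edit distance is the
naive exponential recursion.
"""

from __future__ import annotations

from typing import Iterator, Sequence

from vcase.textnorm import (
    DEFAULT_OOV_FLOOR,
    HmmModel,
    Lexicon,
    segment_log_prob,
    sequence_log_prob,
)

_LEGAL_NEXT = {"B": ("M", "E"), "M": ("M", "E"), "E": ("B", "S"), "S": ("B", "S")}


def all_segmentations(sentence: str, lexicon: Lexicon) -> Iterator[list[str]]:
    """Every tokenisation into lexicon words or single symbols."""
    if not sentence:
        yield []
        return
    for j in range(1, len(sentence) + 1):
        head = sentence[:j]
        if j == 1 or head in lexicon:
            for rest in all_segmentations(sentence[j:], lexicon):
                yield [head] + rest


def best_segmentation_score(
    sentence: str, lexicon: Lexicon, oov_floor: float = DEFAULT_OOV_FLOOR
) -> float:
    return max(
        sum(segment_log_prob(tok, lexicon, oov_floor) for tok in seg)
        for seg in all_segmentations(sentence, lexicon)
    )


def count_paths(sentence: str, lexicon: Lexicon) -> int:
    """Number of admissible segmentations, by exhaustive recursion."""
    return sum(1 for _ in all_segmentations(sentence, lexicon))


def legal_tag_sequences(n: int) -> Iterator[list[str]]:
    """All legal BMES sequences of length n (start B/S, end E/S)."""

    def extend(prefix: list[str]) -> Iterator[list[str]]:
        if len(prefix) == n:
            if prefix[-1] in ("E", "S"):
                yield list(prefix)
            return
        for nxt in _LEGAL_NEXT[prefix[-1]]:
            prefix.append(nxt)
            yield from extend(prefix)
            prefix.pop()

    for start in ("B", "S"):
        yield from extend([start])


def best_tag_score(span: str, model: HmmModel) -> float:
    return max(
        sequence_log_prob(span, tags, model)
        for tags in legal_tag_sequences(len(span))
    )


def naive_edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Textbook exponential recursion (no DP), for short sequences only."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        naive_edit_distance(a[1:], b) + 1,
        naive_edit_distance(a, b[1:]) + 1,
        naive_edit_distance(a[1:], b[1:]) + (a[0] != b[0]),
    )
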