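"""Segmentation stack: trie, word graph, DP path, rules, HMM, negation."""

import math

import numpy as np
import pytest

from conftest import random_sentence
from oracles import (
    best_segmentation_score,
    best_tag_score,
    count_paths,
    legal_tag_sequences,
)
from vcase.fixtures import (
    generate_lexicon,
    generate_reference_hmm,
    generate_tagged_corpus,
    sample_from_hmm,
)
from vcase.textnorm import (
    DEFAULT_RULES,
    Lexicon,
    TaggedCorpus,
    annotate_negation,
    apply_rule_patterns,
    boundary_prf,
    build_trie,
    build_word_graph,
    max_prob_segment,
    segment,
    sequence_log_prob,
    train_hmm,
    viterbi_decode,
    words_from_tags,
)


class TestTrie:
    def test_prefix_and_membership(self):
        trie = build_trie(Lexicon(entries={"ab": 2, "a": 1}))
        assert trie.prefix("a")
        assert trie.member("a")
        assert trie.member("ab")
        assert not trie.member("b")
        assert not trie.prefix("b")

    def test_round_trip_frequencies(self, random_lexicon):
        trie = build_trie(random_lexicon)
        for word, freq in random_lexicon.entries.items():
            assert trie.member(word)
            assert trie.freq(word) == freq

    def test_membership_matches_linear_scan(self, random_lexicon):
        trie = build_trie(random_lexicon)
        words = set(random_lexicon.entries)
        rng = np.random.default_rng(5)
        for _ in range(300):
            probe = random_sentence(rng, "abcd", 4)
            assert trie.member(probe) == (probe in words)


class TestWordGraph:
    def test_hand_enumerable_edges(self):
        lex = Lexicon(entries={"ab": 1, "a": 1, "b": 1})
        graph = build_word_graph("ab", build_trie(lex))
        assert graph.edges == [[1, 2], [2]]

    def test_no_dictionary_match_single_path(self):
        lex = Lexicon(entries={"zz": 1})
        graph = build_word_graph("ab", build_trie(lex))
        assert graph.path_count() == 1

    def test_path_count_matches_recursion_oracle(self, random_lexicon):
        trie = build_trie(random_lexicon)
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = random_sentence(rng, "abcd", 10)
            graph = build_word_graph(s, trie)
            assert graph.path_count() == count_paths(s, random_lexicon)


class TestMaxProbSegment:
    def test_prefers_frequent_whole_word(self, small_lexicon):
        # log(5/15) beats log(3/15)+log(2/15)
        assert max_prob_segment("ab", small_lexicon).tokens == ["ab"]

    def test_single_word_sentence(self, small_lexicon):
        assert max_prob_segment("abc", small_lexicon).tokens == ["abc"]

    def test_spans_tile_sentence(self, random_lexicon):
        rng = np.random.default_rng(13)
        for _ in range(200):
            s = random_sentence(rng, "abcd", 12)
            seg = max_prob_segment(s, random_lexicon)
            assert seg.text == s
            assert seg.spans[0][0] == 0 and seg.spans[-1][1] == len(s)
            for (a, b), (c, d) in zip(seg.spans, seg.spans[1:]):
                assert b == c

    def test_score_equals_exhaustive_enumeration(self, random_lexicon):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = random_sentence(rng, "abcd", 12)
            seg = max_prob_segment(s, random_lexicon)
            assert math.isclose(
                seg.score(random_lexicon),
                best_segmentation_score(s, random_lexicon),
                abs_tol=1e-9,
            )


class TestRulePatterns:
    def test_duration_frozen_as_one_token(self):
        hits = apply_rule_patterns("black stool for 10 days", DEFAULT_RULES)
        assert any(tok == "10 days" and rid == "duration" for _sp, tok, rid in hits)

    def test_no_digits_no_match(self):
        assert apply_rule_patterns("no fever or chills", DEFAULT_RULES) == []

    def test_overlapping_matches_are_disjoint(self):
        rng = np.random.default_rng(23)
        pieces = ["10 days", "2023-04-01", "3.5 mg", "12-15", "7", "xy"]
        for _ in range(100):
            text = " ".join(
                pieces[int(i)] for i in rng.integers(0, len(pieces), size=6)
            )
            spans = [sp for sp, _t, _r in apply_rule_patterns(text, DEFAULT_RULES)]
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 <= a2  # sorted and pairwise disjoint


class TestHmm:
    def test_single_symbol_corpus_concentrates_s(self):
        corpus = TaggedCorpus(
            sentences=[("aba", ["S", "S", "S"]), ("bb", ["S", "S"])]
        )
        model = train_hmm(corpus, smoothing=0.01)
        assert model.log_transition["S"]["S"] > model.log_transition["S"]["B"]

    def test_distributions_sum_to_one(self, random_lexicon):
        corpus = generate_tagged_corpus(random_lexicon, 50, 0.1, seed=3)
        model = train_hmm(corpus)
        for s in "BMES":
            trans = sum(
                math.exp(v)
                for v in model.log_transition[s].values()
                if v > float("-inf")
            )
            assert math.isclose(trans, 1.0, abs_tol=1e-9)
            emit = sum(math.exp(v) for v in model.log_emission[s].values())
            emit += math.exp(model.log_unk[s])
            assert math.isclose(emit, 1.0, abs_tol=1e-9)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_hmm(TaggedCorpus(sentences=[]))

    def test_parameter_recovery_from_known_model(self):
        truth = generate_reference_hmm(alphabet_size=10, seed=41)
        corpus = sample_from_hmm(truth, 4000, seed=42)
        fitted = train_hmm(corpus, smoothing=0.1)
        for s in "BMES":
            for t in "BMES":
                tv, fv = truth.log_transition[s][t], fitted.log_transition[s][t]
                if tv == float("-inf"):
                    assert fv == float("-inf")
                else:
                    assert abs(math.exp(tv) - math.exp(fv)) < 0.05


class TestViterbi:
    def test_length_one_is_s(self):
        model = generate_reference_hmm(seed=1)
        assert viterbi_decode("a", model) == ["S"]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(29)
        for trial in range(60):
            model = generate_reference_hmm(alphabet_size=6, seed=trial)
            span = random_sentence(rng, "abcdef", 6)
            tags = viterbi_decode(span, model)
            assert math.isclose(
                sequence_log_prob(span, tags, model),
                best_tag_score(span, model),
                abs_tol=1e-9,
            )

    def test_invariant_to_constant_log_shift(self):
        model = generate_reference_hmm(alphabet_size=6, seed=8)
        shifted = generate_reference_hmm(alphabet_size=6, seed=8)
        for s in "BMES":
            shifted.log_emission[s] = {
                k: v + 2.5 for k, v in shifted.log_emission[s].items()
            }
            shifted.log_unk[s] += 2.5
        rng = np.random.default_rng(31)
        for _ in range(20):
            span = random_sentence(rng, "abcdef", 8)
            assert viterbi_decode(span, model) == viterbi_decode(span, shifted)

    def test_legal_sequence_enumeration_counts(self):
        # sanity of the oracle itself: legal sequences of length n are the
        # compositions of n into word lengths, i.e. 2**(n-1)
        assert [
            sum(1 for _ in legal_tag_sequences(n)) for n in (1, 2, 3, 4)
        ] == [1, 2, 4, 8]


class TestSegmentPipeline:
    def test_all_dictionary_equals_dp(self, random_lexicon):
        model = generate_reference_hmm(seed=2)
        rng = np.random.default_rng(37)
        vocab = sorted(random_lexicon.entries)
        for _ in range(50):
            s = "".join(
                vocab[int(i)] for i in rng.integers(0, len(vocab), size=4)
            )
            assert (
                segment(s, random_lexicon, model).tokens
                == max_prob_segment(s, random_lexicon).tokens
            )

    def test_oov_run_merged_by_hmm(self):
        # model trained so a 3-symbol unknown span decodes as one B-M-E word
        lex = Lexicon(entries={"zz": 10})
        corpus = TaggedCorpus(
            sentences=[("xyq", ["B", "M", "E"])] * 50
        )
        model = train_hmm(corpus, smoothing=0.01)
        seg = segment("xyq", lex, model)
        assert seg.tokens == ["xyq"]
        assert seg.source == ["OOV"]

    def test_tokens_always_tile_input(self, random_lexicon):
        model = generate_reference_hmm(seed=3)
        rng = np.random.default_rng(43)
        for _ in range(150):
            s = random_sentence(rng, "abcdxyz", 14)
            seg = segment(s, random_lexicon, model, DEFAULT_RULES)
            assert seg.text == s

    def test_boundary_f1_self_is_one(self):
        gold = [["ab", "c"], ["d", "ef"]]
        assert boundary_prf(gold, gold) == (1.0, 1.0, 1.0)

    def test_words_from_tags_splits_at_b_and_s(self):
        assert words_from_tags("abcde", ["B", "E", "S", "B", "E"]) == [
            "ab",
            "c",
            "de",
        ]


class TestNegation:
    QUALIFIERS = ("no", "without", "denies")

    def test_no_qualifier_all_affirmed(self):
        ann = annotate_negation(["fever", "cough"], self.QUALIFIERS)
        assert ann.polarity == ["affirmed", "affirmed"]
        assert ann.qualifier_hits == []

    def test_simple_negation(self):
        ann = annotate_negation(["no", "fever"], self.QUALIFIERS)
        assert ann.polarity == ["qualifier", "negated"]
        assert ann.qualifier_hits == [("no", [1])]

    def test_double_qualifier_flips_back(self):
        ann = annotate_negation(
            ["no", "without", "fever"], self.QUALIFIERS
        )
        assert ann.polarity[-1] == "affirmed"

    def test_clause_bounds_scope(self):
        ann = annotate_negation(
            ["no", "fever", ",", "cough"], self.QUALIFIERS
        )
        assert ann.polarity == ["qualifier", "negated", "delimiter", "affirmed"]
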