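"""Dictionary DAG segmentation with HMM fallback for unknown words.

Builds a small lexicon, trains a BMES character HMM on a tagged corpus
drawn from it, and segments a sentence containing an out-of-vocabulary
word: dictionary words come out of the maximum-probability DP path, the
unknown span is re-decoded character by character.
"""

from vcase.fixtures import generate_lexicon, generate_tagged_corpus
from vcase.textnorm import Lexicon, max_prob_segment, segment, train_hmm

raw = generate_lexicon(alphabet_size=6, n_words=40, seed=1)
# multi-symbol dictionary: single symbols are then only an OOV fallback
lexicon = Lexicon(
    entries={w: f for w, f in raw.entries.items() if len(w) >= 2}
)
corpus = generate_tagged_corpus(lexicon, n_sentences=500, oov_rate=0.2, seed=2)
hmm = train_hmm(corpus, smoothing=0.5)

words = sorted(lexicon.entries, key=lexicon.entries.get, reverse=True)
sentence = words[0] + words[3] + words[5]
seg = segment(sentence, lexicon, hmm)
print(f"sentence: {sentence!r}")
print(f"tokens:   {seg.tokens}  sources: {seg.source}")
print("-> every token is a dictionary word chosen by the max-probability path")

dp_only = max_prob_segment(sentence, lexicon)
assert dp_only.tokens == seg.tokens

# an in-alphabet 3-symbol word none of whose substrings is a dictionary word
from itertools import product

oov_word = next(
    "".join(c)
    for c in product("abcdef", repeat=3)
    if not any(
        "".join(c)[i:j] in lexicon
        for i in range(3)
        for j in range(i + 2, 4)
    )
)
oov_sentence = words[0] + oov_word
seg2 = segment(oov_sentence, lexicon, hmm)
print(f"\nsentence: {oov_sentence!r}")
print(f"tokens:   {seg2.tokens}  sources: {seg2.source}")
print("-> the unknown span is re-decoded into word(s) by the Viterbi BMES tagger")
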