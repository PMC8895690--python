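"""Routing free-text student questions onto the standard question library.

Shows the three routing outcomes: an exact hit (distance 0) returns the
answer, a near miss returns a ranked candidate set to reconfirm, and
off-process text triggers the deviation message. Also demonstrates synonym
conversion: a colloquial token is replaced by its cosine-nearest standard
term before matching.
"""

from vcase.fixtures import make_case_fixture
from vcase.matching import NlpPipeline, match_question, train_vectors
from vcase.textnorm import Lexicon

fx = make_case_fixture("inguinal_hernia", seed=0)
q = fx.library.questions[0]

exact = match_question(q.display_text, fx.library, fx.pipeline)
print(f"exact:   {exact.outcome.value}  answer={exact.matched.answer_text!r}")

near_text = "zzz" + q.display_text[3:]  # one token perturbed
near = match_question(near_text, fx.library, fx.pipeline)
print(
    f"near:    {near.outcome.value}  "
    f"candidates={[(c.question_id, d) for c, d in near.candidates]}"
)

far = match_question("qqqppprrrsssttt", fx.library, fx.pipeline)
print(f"far:     {far.outcome.value}  message={far.message!r}")
print("-> distance 0 / under 5 / 5-or-more partition every input")

# synonym conversion: 'xyz' is trained interchangeable with standard 'abc'
lex = Lexicon(entries={"abc": 5, "xyz": 5, "def": 5})
vectors = train_vectors(
    [["abc", "def"], ["xyz", "def"]] * 20, dim=4, seed=0,
    standard_terms=["abc", "def"],
)
pipe = NlpPipeline(lexicon=lex, vectors=vectors, similarity_threshold=0.5)
tokens, _ = pipe.normalize("xyzdef")
print(f"\nsynonyms: 'xyzdef' normalises to {tokens}")
print("-> the colloquial token was replaced by its nearest standard term")
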