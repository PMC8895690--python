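import numpy as np
import pytest

from vcase.fixtures import generate_lexicon, make_case_fixture
from vcase.textnorm import Lexicon


@pytest.fixture(scope="session")
def small_lexicon() -> Lexicon:
    return Lexicon(entries={"ab": 5, "a": 3, "b": 2, "abc": 4, "bc": 1})


@pytest.fixture(scope="session")
def random_lexicon() -> Lexicon:
    return generate_lexicon(alphabet_size=4, n_words=30, seed=11)


@pytest.fixture(scope="session")
def hernia_fixture():
    return make_case_fixture("inguinal_hernia", seed=3)


def random_sentence(rng: np.random.Generator, alphabet: str, max_len: int) -> str:
    n = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n))
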