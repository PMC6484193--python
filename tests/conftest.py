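import numpy as np
import pytest

from aoanet import Lexicon, LexiconConfig, WordItem, generate_lexicon


@pytest.fixture(scope="session")
def default_lexicon() -> Lexicon:
    """The full 327-item synthetic lexicon with the standard group sizes."""
    return generate_lexicon(LexiconConfig(seed=11))


@pytest.fixture()
def tiny_lexicon() -> Lexicon:
    """Three hand-written items over small alphabets for exact checks."""
    items = [
        WordItem("a", (1, 2, 3, -1), (0, 1, 2, -1), grade=1, frequency=1),
        WordItem("b", (1, 2, 4, -1), (0, 1, 3, -1), grade=1, frequency=2),
        WordItem("c", (5, 6, 7, -1), (4, 5, 6, -1), grade=2, frequency=1),
    ]
    return Lexicon(items, n_letters=8, n_phonemes=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
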