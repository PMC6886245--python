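import numpy as np
import pytest

from bactner.corpus import Corpus, Sentence, Token
from bactner.lexicon import Lexicon

# The worked example sentence used throughout: three oral pathogens joined
# by punctuation and a conjunction, in the 4-column corpus format.
EXAMPLE_ROWS = [
    ("Actinobacillus", "NNP", "B-bacteria", "B-bacteria"),
    ("actinomycetemcomitans", "NNS", "I-bacteria", "I-bacteria"),
    (",", ",", "O", "O"),
    ("Porphyromonas", "NNP", "B-bacteria", "B-bacteria"),
    ("gingivalis", "NN", "I-bacteria", "I-bacteria"),
    (",", ",", "O", "O"),
    ("and", "CC", "O", "O"),
    ("Peptostreptococcus", "NNP", "B-bacteria", "B-bacteria"),
    ("micros", "NNS", "I-bacteria", "I-bacteria"),
]

EXAMPLE_LEXICON_NAMES = [
    "Actinobacillus actinomycetemcomitans",
    "Porphyromonas gingivalis",
    "Peptostreptococcus micros",
]


@pytest.fixture
def example_sentence() -> Sentence:
    return Sentence(tuple(Token(*row) for row in EXAMPLE_ROWS))


@pytest.fixture
def example_corpus(example_sentence) -> Corpus:
    return Corpus((example_sentence,))


@pytest.fixture
def example_conll_text() -> str:
    return "".join("\t".join(row) + "\n" for row in EXAMPLE_ROWS) + "\n"


@pytest.fixture
def example_lexicon() -> Lexicon:
    return Lexicon(tuple(name.split()) for name in EXAMPLE_LEXICON_NAMES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
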