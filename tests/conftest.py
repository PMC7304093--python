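import numpy as np
import pytest

from anotext.lexicons import AffectiveWordList, DifficultyLexicons, PolarityLexicon
from anotext.textprep import BasicFormMap, RawDocument, StopList, TermBag


@pytest.fixture
def polarity_lexicon():
    return PolarityLexicon({"good": 1, "great": 1, "bad": -1, "awful": -1})


@pytest.fixture
def affective_list():
    # one clearly dominant emotion per term on the default [1, 7] scale
    return AffectiveWordList(1.0, 7.0, {
        "cage": {"happiness": 1.2, "anger": 2.0, "sadness": 5.9, "fear": 4.1,
                 "disgust": 1.5},
        "tears": {"happiness": 1.0, "anger": 1.5, "sadness": 7.0, "fear": 2.0,
                  "disgust": 1.0},
        "spider": {"happiness": 1.0, "anger": 2.0, "sadness": 2.0, "fear": 6.4,
                   "disgust": 4.0},
        "sunshine": {"happiness": 6.7, "anger": 1.0, "sadness": 1.0, "fear": 1.0,
                     "disgust": 1.0},
    })


@pytest.fixture
def difficulty_dicts():
    return DifficultyLexicons({
        "body-image": frozenset({"fat", "thighs"}),
        "emotions": frozenset({"hate", "fat"}),
    })


@pytest.fixture
def stoplist():
    return StopList(frozenset({"i", "a", "the"}))


@pytest.fixture
def basic_forms():
    return BasicFormMap({"ate": "eat", "eats": "eat", "fats": "fat"})


def make_bag(doc_id="d", **counts) -> TermBag:
    return TermBag(doc_id, counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
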