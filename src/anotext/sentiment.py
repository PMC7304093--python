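"""Dictionary sentiment: the order-blind polarity score of a statement.

The score counts polarity-lexicon matches in the basic-form term bag with
multiplicity and reports

    S = (P - N) / (P + N)

where P and N are the matched positive and negative token counts; S = 0
when nothing matches.  The class is sign(S) in {-1, 0, +1}, so a document
is neutral exactly when its score is zero.  Strength tags of the lexicon
are ignored (unweighted counts): the per-document scores this reproduces
are plain rationals such as 1/3 or -9/11.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicons import PolarityLexicon
from .textprep import TermBag

__all__ = ["DictSentimentResult", "score_document"]


@dataclass(frozen=True)
class DictSentimentResult:
    """Quantitative dictionary sentiment of one document."""

    doc_id: str
    n_pos: int
    n_neg: int
    value: float
    klass: int

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "value": self.value,
            "class": self.klass,
        }


def score_document(bag: TermBag, lex: PolarityLexicon) -> DictSentimentResult:
    """Score a basic-form term bag against a polarity lexicon.

    Deterministic and total: a bag with no lexicon matches scores 0.0 with
    the neutral class.
    """
    n_pos = 0
    n_neg = 0
    for term, count in bag.counts.items():
        pol = lex.polarity(term)
        if pol > 0:
            n_pos += count
        elif pol < 0:
            n_neg += count
    matched = n_pos + n_neg
    value = (n_pos - n_neg) / matched if matched else 0.0
    klass = (value > 0) - (value < 0)
    return DictSentimentResult(bag.doc_id, n_pos, n_neg, value, klass)
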