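"""Difficulty-area scoring: relative frequency of area-dictionary matches.

Six clinician-defined categories describe where a patient's difficulties
concentrate: self-esteem, acceptance of the social assessment, emotions,
autoimmune (aggressive and self-aggressive behaviour), functioning of the
body, and body image.  Each area holds a term dictionary; the score of an
area is the fraction of the document's basic-form tokens (with
multiplicity) matching that dictionary, hence a value in [0, 1] suitable
for a radar chart.  A term listed under several areas contributes to each
of them — the categories overlap semantically and exclusivity is not
assumed.  The relative-frequency form of the score is this package's
reconstruction (the source study fixes the categories, not the formula).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .lexicons import AREAS, DifficultyLexicons
from .textprep import TermBag

__all__ = ["DifficultyProfile", "profile_areas"]


@dataclass(frozen=True)
class DifficultyProfile:
    """Scores for all six canonical areas, each in [0, 1]."""

    doc_id: str
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.scores) != set(AREAS):
            raise ValueError(f"scores must cover exactly the areas {AREAS}")
        for area, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {area}={s} outside [0, 1]")

    def to_dict(self) -> dict:
        return {area: self.scores[area] for area in AREAS}


def profile_areas(bag: TermBag, dicts: DifficultyLexicons) -> DifficultyProfile:
    """Relative match frequency of each difficulty area in a term bag.

    An empty bag scores 0 everywhere.  Duplicating every token count
    leaves all scores unchanged.
    """
    total = bag.total()
    scores = {}
    for area in AREAS:
        terms = dicts.areas[area]
        matched = sum(c for t, c in bag.counts.items() if t in terms)
        scores[area] = matched / total if total else 0.0
    return DifficultyProfile(bag.doc_id, scores)
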