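"""Emotion-intensity profiling from an affective word list.

A one-level taxonomy assigns each affective-list term to at most one of
the five basic emotion groups (happiness, anger, sadness, fear, disgust):
a term joins the group of its strictly maximal rating, provided that
rating reaches the threshold θ (default: the scale midpoint); ties for
the maximum, or a maximum below θ, leave the term unassigned.

Document intensity per emotion is the mean, over contributing matched
tokens counted with multiplicity, of the min-max-normalized rating
(r - lo) / (hi - lo) — a value in [0, 1].  An emotion with no contributing
token is *absent* from the profile, which is distinct from intensity 0:
short statements frequently match no affective term at all.

The group-assignment rule and the mean-normalized-rating intensity are a
documented reconstruction: the underlying study describes the taxonomy
and the [0, 1] output range but not the exact membership formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .lexicons import EMOTIONS, AffectiveWordList
from .textprep import TermBag

__all__ = ["EmotionTaxonomy", "EmotionProfile", "assign_group", "profile_document"]


@dataclass(frozen=True)
class EmotionTaxonomy:
    """Membership rule parameters: threshold θ on the raw rating scale.

    ``threshold=None`` resolves to the scale midpoint of the word list in
    use, e.g. 4.0 on a [1, 7] scale.
    """

    threshold: float | None = None

    def resolve_threshold(self, awl: AffectiveWordList) -> float:
        theta = self.threshold if self.threshold is not None else awl.midpoint
        if not awl.scale_lo <= theta <= awl.scale_hi:
            raise ValueError(
                f"threshold {theta} outside rating scale "
                f"[{awl.scale_lo}, {awl.scale_hi}]"
            )
        return theta


@dataclass(frozen=True)
class EmotionProfile:
    """Partial map emotion -> intensity in [0, 1]; absent means no match."""

    doc_id: str
    intensity: Mapping[str, float]

    def __post_init__(self) -> None:
        for emo, value in self.intensity.items():
            if emo not in EMOTIONS:
                raise ValueError(f"unknown emotion {emo!r}")
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"intensity {emo}={value} outside [0, 1]")

    def to_dict(self) -> dict:
        """All five emotions, absent ones serialized as None (blank cells)."""
        return {emo: self.intensity.get(emo) for emo in EMOTIONS}


def assign_group(
    ratings: Mapping[str, float],
    tax: EmotionTaxonomy,
    awl: AffectiveWordList,
) -> str | None:
    """Emotion group of one rating vector, or None.

    Returns the emotion whose rating is the strict maximum of the vector
    when that maximum is >= θ; None on a tie for the maximum or when the
    maximum falls below θ.
    """
    theta = tax.resolve_threshold(awl)
    best = max(ratings[e] for e in EMOTIONS)
    if best < theta:
        return None
    winners = [e for e in EMOTIONS if ratings[e] == best]
    if len(winners) != 1:
        return None
    return winners[0]


def profile_document(
    bag: TermBag,
    awl: AffectiveWordList,
    tax: EmotionTaxonomy | None = None,
) -> EmotionProfile:
    """Estimate per-emotion intensity of a basic-form term bag.

    Repeated words reinforce intensity through the mean's weighting
    (multiplicity counts).  Token order never matters.
    """
    tax = tax if tax is not None else EmotionTaxonomy()
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for term, count in bag.counts.items():
        ratings = awl.entries.get(term)
        if ratings is None:
            continue
        emo = assign_group(ratings, tax, awl)
        if emo is None:
            continue
        sums[emo] = sums.get(emo, 0.0) + awl.normalize(ratings[emo]) * count
        counts[emo] = counts.get(emo, 0) + count
    intensity = {emo: sums[emo] / counts[emo] for emo in sums}
    return EmotionProfile(bag.doc_id, intensity)
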