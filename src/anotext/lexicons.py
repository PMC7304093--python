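"""Lexicon resources: polarity lexicon, affective word list, difficulty dictionaries.

Three dictionary resources drive the pipeline's dictionary stages:

* a **polarity lexicon** mapping basic-form terms to {-1, +1} (the
  Wilson–Wiebe–Hoffmann subjectivity-clues format is one accepted dialect);
* an **affective word list** with per-term intensity ratings for the five
  basic emotions (happiness, anger, sadness, fear, disgust) on a declared
  numeric scale, format-compatible with the Nencki Affective Word List;
* six clinician-defined **difficulty-area dictionaries** (term sets).

Licensed resources (NAWL, BAWL-R, the MPQA lexicon) are never bundled;
loaders accept user-supplied exports, and the synthetic module generates
format-compatible stand-ins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "EMOTIONS",
    "AREAS",
    "PolarityLexicon",
    "AffectiveWordList",
    "DifficultyLexicons",
    "read_polarity_lexicon",
    "write_polarity_lexicon",
    "read_affective_list",
    "write_affective_list",
    "read_difficulty_dicts",
    "write_difficulty_dicts",
]

#: The five basic emotions, in canonical column order.
EMOTIONS = ("happiness", "anger", "sadness", "fear", "disgust")

#: Canonical slugs of the six clinician-defined areas of difficulty.
AREAS = (
    "self-esteem",
    "acceptance-of-social-assessment",
    "emotions",
    "autoimmune",
    "functioning-of-the-body",
    "body-image",
)


@dataclass(frozen=True)
class PolarityLexicon:
    """Term -> polarity in {-1, +1}, with an optional weak/strong tag."""

    entries: Mapping[str, int]
    strength: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, pol in self.entries.items():
            if pol not in (-1, 1):
                raise ValueError(f"polarity of {term!r} must be -1 or +1, got {pol}")
            if term != term.lower():
                raise ValueError(f"lexicon term {term!r} must be lowercase")

    def __len__(self) -> int:
        return len(self.entries)

    def polarity(self, term: str) -> int:
        """Polarity of ``term``: -1, +1, or 0 when absent."""
        return self.entries.get(term, 0)

    def negated(self) -> "PolarityLexicon":
        """The lexicon with every polarity flipped (used in property checks)."""
        return PolarityLexicon(
            {t: -p for t, p in self.entries.items()}, dict(self.strength)
        )


@dataclass(frozen=True)
class AffectiveWordList:
    """Term -> five-emotion rating vector on the scale [scale_lo, scale_hi]."""

    scale_lo: float
    scale_hi: float
    entries: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if not self.scale_lo < self.scale_hi:
            raise ValueError("scale_lo must be < scale_hi")
        for term, ratings in self.entries.items():
            missing = set(EMOTIONS) - set(ratings)
            if missing:
                raise ValueError(f"term {term!r} missing emotions {sorted(missing)}")
            for emo in EMOTIONS:
                r = ratings[emo]
                if not self.scale_lo <= r <= self.scale_hi:
                    raise ValueError(
                        f"rating {emo}={r} of term {term!r} outside "
                        f"[{self.scale_lo}, {self.scale_hi}]"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def midpoint(self) -> float:
        return (self.scale_lo + self.scale_hi) / 2.0

    def normalize(self, rating: float) -> float:
        """Map a raw rating to [0, 1] over the declared scale."""
        return (rating - self.scale_lo) / (self.scale_hi - self.scale_lo)


@dataclass(frozen=True)
class DifficultyLexicons:
    """The six difficulty-area term sets; all six keys always present."""

    areas: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = set(self.areas) - set(AREAS)
        if unknown:
            raise ValueError(f"unknown difficulty areas: {sorted(unknown)}")
        # fill absent areas with empty sets
        full = {a: frozenset(self.areas.get(a, frozenset())) for a in AREAS}
        object.__setattr__(self, "areas", full)


# ---------------------------------------------------------------------------
# polarity lexicon IO


def _parse_mpqa_line(line: str) -> dict[str, str]:
    fields = {}
    for chunk in line.split():
        if "=" not in chunk:
            raise ValueError(f"malformed field {chunk!r}")
        key, value = chunk.split("=", 1)
        fields[key] = value
    return fields


def read_polarity_lexicon(path: str | Path, dialect: str = "tsv") -> PolarityLexicon:
    """Read a polarity lexicon.

    ``tsv`` dialect: two columns ``term<TAB>polarity`` with polarity ``+1``
    or ``-1``.  ``mpqa`` dialect: the subjectivity-clues line grammar
    (``type=… word1=… priorpolarity=…``); ``priorpolarity`` of ``positive``
    / ``negative`` maps to +1 / -1, ``neutral`` and ``both`` entries are
    dropped, and ``type`` strongsubj/weaksubj becomes the strength tag.

    Duplicate terms with conflicting polarity raise an error naming the line.
    """
    if dialect not in ("tsv", "mpqa"):
        raise ValueError(f"unknown dialect {dialect!r}")
    entries: dict[str, int] = {}
    strength: dict[str, str] = {}
    text = Path(path).read_text(encoding="utf-8-sig")
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "tsv":
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{i}: expected 'term<TAB>polarity'")
            term = parts[0].strip().lower()
            try:
                pol = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{i}: polarity {parts[1]!r} not an integer")
            if pol not in (-1, 1):
                raise ValueError(f"{path}:{i}: polarity must be +1 or -1, got {pol}")
            tag = None
        else:
            try:
                fields = _parse_mpqa_line(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: {exc}")
            if "word1" not in fields or "priorpolarity" not in fields:
                raise ValueError(f"{path}:{i}: missing word1/priorpolarity field")
            prior = fields["priorpolarity"]
            if prior in ("neutral", "both"):
                continue
            if prior not in ("positive", "negative"):
                raise ValueError(f"{path}:{i}: unknown priorpolarity {prior!r}")
            term = fields["word1"].lower()
            pol = 1 if prior == "positive" else -1
            tag = {"strongsubj": "strong", "weaksubj": "weak"}.get(fields.get("type", ""))
        if term in entries and entries[term] != pol:
            raise ValueError(f"{path}:{i}: term {term!r} has conflicting polarities")
        entries[term] = pol
        if tag is not None:
            strength[term] = tag
    return PolarityLexicon(entries, strength)


def write_polarity_lexicon(lex: PolarityLexicon, path: str | Path) -> None:
    """Write the simple TSV dialect (strength tags are not serialized)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lex.entries):
            fh.write(f"{term}\t{lex.entries[term]:+d}\n")


# ---------------------------------------------------------------------------
# affective word list IO

_AWL_HEADER = ("term",) + EMOTIONS


def read_affective_list(
    path: str | Path, scale_lo: float = 1.0, scale_hi: float = 7.0
) -> AffectiveWordList:
    """Read a CSV with header ``term,happiness,anger,sadness,fear,disgust``.

    Ratings outside the declared scale raise an error naming the term.  The
    default [1, 7] scale follows 7-point category-rating conventions of the
    BAWL-R lexicon family; pass the bounds of your export if they differ.
    """
    entries: dict[str, dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header")
        if tuple(h.strip().lower() for h in header) != _AWL_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(_AWL_HEADER)}, got {','.join(header)}"
            )
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 6:
                raise ValueError(f"{path}: row for {row[0]!r} must have 6 columns")
            term = row[0].strip().lower()
            ratings = {}
            for emo, cell in zip(EMOTIONS, row[1:]):
                r = float(cell)
                if not scale_lo <= r <= scale_hi:
                    raise ValueError(
                        f"{path}: rating {emo}={r} of term {term!r} outside "
                        f"[{scale_lo}, {scale_hi}]"
                    )
                ratings[emo] = r
            entries[term] = ratings
    return AffectiveWordList(scale_lo, scale_hi, entries)


def write_affective_list(awl: AffectiveWordList, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_AWL_HEADER)
        for term in sorted(awl.entries):
            ratings = awl.entries[term]
            writer.writerow([term] + [repr(float(ratings[e])) for e in EMOTIONS])


# ---------------------------------------------------------------------------
# difficulty dictionaries IO


def read_difficulty_dicts(path: str | Path) -> DifficultyLexicons:
    """Read a TSV ``area<TAB>term``; unlisted areas come back as empty sets.

    Duplicate (area, term) rows collapse (set semantics); a term may appear
    under several areas — the categories overlap conceptually.
    """
    areas: dict[str, set[str]] = {a: set() for a in AREAS}
    for i, line in enumerate(
        Path(path).read_text(encoding="utf-8-sig").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 'area<TAB>term'")
        area = parts[0].strip().lower()
        if area not in areas:
            raise ValueError(f"{path}:{i}: unknown area {area!r}")
        areas[area].add(parts[1].strip().lower())
    return DifficultyLexicons({a: frozenset(s) for a, s in areas.items()})


def write_difficulty_dicts(dicts: DifficultyLexicons, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for area in AREAS:
            for term in sorted(dicts.areas[area]):
                fh.write(f"{area}\t{term}\n")
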